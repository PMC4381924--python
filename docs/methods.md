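# Methods

This note documents the models implemented in `memfret`, the corrections
and numerical choices, what the synthetic generators do and do not emulate,
and the package's known limitations.

## FRET photophysics

Pairwise transfer efficiency follows Förster theory,
E(r) = 1/(1 + (r/R₀)⁶). The Förster radius is computed from the overlap
integral J = ∫f_D(λ)ε_A(λ)λ⁴dλ / ∫f_D(λ)dλ (trapezoidal, union grid,
common window) as R₀ = 0.211·(κ²n⁻⁴Q_D J)^{1/6} Å with J in
M⁻¹cm⁻¹nm⁴. Defaults κ² = 2/3 and n = 1.33 describe freely rotating
fluorophores in an aqueous environment; only the resulting radii matter
downstream.

No measured spectra ship with the package. `memfret.reference` builds
*synthetic* skew-normal approximations to the published band shapes of
mTurquoise, EYFP and mCherry (tabulated peak positions, widths and
extinction maxima). With those shapes the computed radii are ≈ 55.0 Å
(mTurquoise→EYFP) and ≈ 55.0 Å (EYFP→mCherry), in the mid-50-Å range
expected for these pairs. Quantitative radii from real measurements require
user-supplied spectra (two-column CSV via `Spectrum.from_csv`).

### Spectral apparent efficiency

The sensitized-emission estimator is
Eapp = [1 + (Q_A/Q_D)(k^DA/k^AD)(w^D/w^A)]⁻¹ with k^DA, k^AD the
maximum emission intensities from a non-negative least-squares decomposition
onto unit-peak reference spectra, and w the spectrum integrals. This is the
unique grouping consistent with photon bookkeeping: donor photons scale as
Q_D(1−E)w^D, sensitized acceptor photons as Q_A·E·w^A. References are
stored unit-peak normalized precisely so the amplitudes are "maximum
emission intensities".

### Donor-quenching efficiency and reconstruction

In the vesicle assay Eapp = 1 − I_D/I_D,corr, where the unquenched donor
intensity is reconstructed by energy conservation,
I_D,corr = I_D + (Q_D/Q_A)·g·F_sens, with g the donor/FRET-channel
detection-efficiency ratio from calibration. Small negative efficiencies
produced by noise are *kept and flagged*, never clipped: clipping would
bias the horizontal-line fits of low-FRET constructs.

### Random-proximity FRET

Donors and acceptors that do not interact still transfer energy when they
randomly co-localize. The reference model is Monte Carlo: Poisson-number
donors and acceptors uniform on a periodic patch (side ≥ 50·R₀), acceptor
placements within a hard-core exclusion radius of any donor re-drawn, and
per-donor efficiency S/(1+S) with S = Σ(R₀/r)⁶ (minimum-image distances,
8·R₀ interaction cutoff). The closed-form cross-check is exact for this
model: writing 1/(1+S) = ∫e^{−(1+S)τ}dτ and taking the Poisson
expectation,

E_prox = 1 − ∫₀^∞ e^{−τ} exp( −σ_A ∫_{r_ex}^∞ (1 − e^{−τ(R₀/r)⁶}) 2πr dr ) dτ,

whose small-density limit is the familiar first-order integral
σ_A∫E(r)·2πr dr. The two agree within Monte-Carlo error at all densities
used here.

**Exclusion radius.** Default 55 Å. Two receptors tagged with
fluorescent-protein barrels cannot bring their fluorophores arbitrarily
close: the intra-dimer fluorophore separation implied by a dimer efficiency
of ≈ 0.38 at R₀ ≈ 53–55 Å is ≈ 58 Å, and receptors merely in contact are
no closer. A 10 Å "bare protein" core would put β-barrels inside one
another. The same radius is used by the scene generator and by the
proximity correction, keeping generator and analysis physics identical.

**Mixture correction.** Transfer rates compete: a donor already transferring
to its dimer partner (rate S_p = Ẽ/(1−Ẽ)) gains less efficiency from a
random neighbour than a monomeric donor does. Subtracting the *monomer*
proximity value from a partly dimerized population therefore over-corrects,
increasingly so at high density, which would bias the fitted plateau low.
The per-bin correction can instead be evaluated for the mixed population,

E_prox(mix) = p·(E[(S_p+S)/(1+S_p+S)] − Ẽ) + (1−p)·E[S/(1+S)],

with p the fraction of donors holding an acceptor partner. Since p and Ẽ
are unknown before fitting, the vesicle study iterates once: fit with the
monomer correction, then re-correct each bin using the fitted (Ẽ, K_d) and
that bin's mean x_a, and refit. One iteration suffices because the
correction is a small perturbation (≤ ~0.04 efficiency units at the highest
densities studied).

## Synthetic scenes and renders

### Monomer–dimer equilibrium

The two-state association model is 2-D mass action: K_d = M²/D
(molecules/µm²), T = M + 2D, solved in the cancellation-free form
M = 2T/(1+√(1+8T/K_d)) so mass conservation holds to 1e-12 at any K_d.
The dimer fraction 2D/T rises from 0 to 1 with density; its plateau-scaled
version Ẽ·f(T;K_d) is the fitted association curve.

### Scenes

A scene is a Poisson draw of monomers and dimers at the equilibrium
densities on a periodic rectangular patch; each molecule is labeled
acceptor with probability x_a, donor otherwise, then dark with an
independent dark fraction (immature fluorophores occupy dimer slots
silently). Dimer partners sit at the separation implied by the configured
pairwise efficiency, at uniformly random orientation. Per-donor efficiency
is rate-additive over the partner (if a visible acceptor) and all unrelated
acceptors beyond the exclusion radius; non-partner pairs closer than the
exclusion radius are treated as excluded volume and skipped, mirroring the
rejection step of the proximity Monte Carlo.

### Vesicle renders

The scene strip (length = equatorial circumference, height = optical
section height, default 1 µm) wraps onto the bright ring. Per-channel
molecule counts are: donor scan gain·Q_D(1−E_i) per donor; FRET scan
gain·Q_A·E_i sensitized per donor, plus donor bleed-through
(fraction 0.12) and directly excited acceptor signal (fraction 0.08);
acceptor scan gain·Q_A per acceptor. Amplitudes are binned in angle,
blurred tangentially by the PSF width (the PSF is isotropic, not purely
radial), and spread radially as a Gaussian (σ = 0.2 µm) on an
error-function step between interior and exterior backgrounds, then Poisson
shot noise and Gaussian read noise are applied. Defaults: 128×128 px at
0.1 µm/px, vesicle radii 2–4 µm, gains 40 counts/molecule-photon,
backgrounds 6 (lumen) / 2 (bath) counts/px, read noise 2 counts — vesicles
imaged in clean buffer have low backgrounds relative to membrane signal,
and these settings put the per-vesicle Eapp precision at the few-percent
level typical of the assay.

What the generator does *not* emulate: vesicle shape irregularity,
z-sectioning and out-of-focus light, flat-field structure, chromatic
offsets between scans, photobleaching, and receptor clustering beyond
dimers. Passing tests therefore demonstrate correctness of the estimators
under the stated optical model, not robustness to every real-microscope
artifact.

### Spectral renders

Each pixel's spectrum is k^DA·f_D(λ) + k^AD·f_A(λ) with amplitudes chosen
so the spectral estimator returns exactly that pixel's ground-truth Eapp
and the summed counts match the requested intensity; optional Poisson noise
per wavelength plane. Live-cell presets draw ground-truth pixel values from
normal distributions truncated to [0, 1] (the estimator's support). A
cell-outline generator (bright 2-px membrane ring, dim interior, dark
exterior) provides ground truth for masking tests.

### Kinetics data

v(S) = k_cat·E₀·S/(K_m+S) with multiplicative lognormal noise of unit mean
and chosen CV per replicate. The preset parameter sets and ATP
concentration series are the published assay values; they are *inputs* to
the generator, and the tests check that the fitters recover them.

## Vesicle quantitation

Detection segments the Gaussian-smoothed sum of the three scans, finds each
region's radial intensity peak around its intensity-weighted centroid (the
ring), and applies QC: ≥ 60 ring pixels, ring-radius spread over angle
≤ 10% of the radius (circularity ≥ 0.9), angular coverage ≥ 90%, a
membrane peak ≥ 30% above the lumen level (rejects filled-disk background
artifacts), and presence in all three scans. Presence compares the ring
peak against the midpoint of flanking annuli: for a channel containing only
the interior/exterior background step, the error-function midpoint at the
ring equals that flank average, so a signal-free channel nulls out exactly
while a dim real membrane still clears the standard error of the mean.

Profiles are sampled along radial normals at 1° spacing (cubic spline
interpolation), averaged after alignment on the fitted ring, over ±1 µm.
The three scans view the same vesicle through the same PSF, so the profile
geometry (center, Gaussian width, step width) is fitted once on the summed
profile — with the step width tied to the Gaussian width, both being set by
the PSF — and each channel's amplitudes are then solved linearly on the
fixed shape basis. The linear solve is the important choice: independent
nonlinear per-channel fits can trade amplitude against baseline-step width
at low signal-to-noise and systematically inflate weak channels (worst for
the FRET channel), which propagates into Eapp. A first fit also refines the
detected ring radius before final sampling. Membrane intensity per µm² is
A·σ√(2π)/pixel² divided by the optical section height; densities follow
from standard-solution slopes (counts per molecule). QC thresholds: summed
and donor profile R² ≥ 0.95, donor amplitude ≥ 3× read noise; excluded
vesicles are logged with reasons and never affect other vesicles.

## Binning and model fits

Vesicles are sorted by total density into equal-count bins of ≥ 8; per-bin
means and spreads (s.e.m. by default, s.d. optional — reporting conventions
vary) are reported in both axes. The association fit is weighted least
squares of Ẽ·f(T;K_d) with 1/spread² weights (zero spreads receive the
median positive weight), multi-start over a log-spaced K_d grid, standard
errors from the Jacobian covariance, and honest flags for non-convergence,
plateau-at-zero, and unidentifiable K_d (saturated data). The horizontal
fit is the inverse-variance-weighted mean. Model choice uses AIC with a
Δ ≥ 2 rule, otherwise "indeterminate". In the K_d→0 constrained limit the
association fit reproduces the horizontal fit exactly.

## Histogram fits

Per-pixel efficiency samples are fitted by maximum likelihood with
truncated normals on the observable support — default (0, 1), since NNLS
amplitudes confine Eapp to that interval; the bounds are a parameter for
data that can spill outside. Reporting the *underlying* normal mean matters
for broad distributions near the boundary: the unliganded population
(mean 0.21, s.d. 0.13) is materially truncated at 0, and a plain normal
fit would be biased high by ≈ +0.015. Two-component fits use multi-start
Nelder–Mead on the mixture likelihood, order components by descending peak,
and flag fits as "unidentifiable" when peak separation is below half the
pooled width or one component carries < 5% of the mass — reported, not
suppressed. Degenerate (zero-variance) samples are flagged.

## Kinetics

Michaelis–Menten fits use `scipy.optimize.curve_fit` with V_max₀ = max v
and K_m₀ = median S. Duplicates are fitted jointly for the headline
parameters; per-replicate fits give the parameter standard deviations.
k_cat is per supplied active-site concentration. When the fitted K_m
exceeds the largest substrate concentration the data contain no curvature,
and the result is reported as a censored lower bound (K_m > max S) with a
flag. Specificity constants are rounded to 2 significant figures for
reporting, with the unrounded identity (k_cat/K_m)·K_m = k_cat preserved.
Linear-range diagnostics require R² ≥ 0.98 against time and enzyme
concentration and < 10% turnover of the limiting substrate.

## Study presets

Vesicle presets: `tm_only` (K_d = 150 µm⁻², Ẽ = 0.38, densities
100–2000 µm⁻²) is the concentration-driven dimerizer; `ecd_tm_unliganded`
(Ẽ = 0.21), `ecd_tm_liganded` (0.34), `ecd_dl1` (0.36) and `h905c` (0.38)
are constitutive dimers (K_d = 10⁻³ µm⁻², dimer fraction > 0.999 across
their 100–1000 µm⁻² range — full-ECD constructs express lower than the
isolated TM); `monomer_control` (K_d = 10⁹ µm⁻²) shows proximity FRET
only. All use x_a = 0.5 (equal-mass co-transfection). The unliganded
constitutive preset represents one of two physical readings of a
low-plateau horizontal line (dimers with low pairwise efficiency); a
Kd-based partial-dimer alternative can be composed from `SceneParams`
directly — the data do not distinguish them and the package does not assert
either. Live-cell presets: single normals (0.34, 0.09) and (0.21, 0.13),
and a two-component (0.37/0.03 + 0.33/0.11) population. Kinetics presets
carry the published parameter sets and ATP grids for five enzyme forms.

## Problem sizes

Default study sizes — 100 vesicles per construct, 10,000 spectral pixels,
100 Monte-Carlo realizations per proximity estimate, 25–120-seed
ensembles in statistical tests — were chosen so each quantity's sampling
error sits comfortably inside the tolerance being checked while a full
analysis completes in seconds on one CPU.

## Known limitations

- The proximity model and generator share one exclusion radius; real
  membranes have softer, anisotropic contact geometry.
- Per-pixel spectral analysis assumes the two reference spectra are exact;
  detector spectral-response drift is out of scope.
- The mixture proximity correction assumes the association model's
  composition estimate; for strongly mis-specified models it reverts in
  effect to the monomer correction.
- The horizontal/association choice by AIC on ≤ ~12 bins has limited power
  near the boundary; the "indeterminate" verdict is returned rather than a
  forced choice.
- Kinetics fits treat each velocity point as independent with equal
  variance; heteroscedastic weighting would be preferable for data with
  strongly intensity-dependent error.
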