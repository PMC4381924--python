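# memfret

Quantitative imaging FRET (QI-FRET) and steady-state kinetics analysis for
membrane-receptor dimerization studies — built around the question of how a
receptor tyrosine kinase's transmembrane (TM) helices move when ligand
binds. The package implements the two complementary FRET workflows used to
measure TM separation in cells and membrane-derived vesicles, the
corrections that turn raw intensities into *intrinsic* FRET, the
monomer–dimer association fit that extracts a 2-D dissociation constant and
the pairwise dimer FRET efficiency, and the Michaelis–Menten workflow used
to characterize the receptor's kinase activity. A synthetic-data module
generates the microscopy and enzymology raw data the pipelines consume, so
every analysis step can be validated against known ground truth.

## The measurements

**Spectrally resolved FRET (live cells).** A two-photon scan records a full
emission spectrum (450–600 nm, 1 nm steps) per pixel. Each pixel spectrum
is decomposed by non-negative least squares onto unit-peak donor and
acceptor reference spectra, giving amplitudes k<sup>DA</sup> and
k<sup>AD</sup>, and the apparent FRET efficiency

    Eapp = [ 1 + (Q_A/Q_D) · (k^DA/k^AD) · (w^D/w^A) ]⁻¹

with quantum yields Q and emission-spectrum integrals w. Histograms of
per-pixel Eapp over membrane pixels are fitted with (mixtures of) truncated
normals; the reported "peak" is the underlying normal mean.

**QI-FRET (vesicles).** Plasma-membrane–derived vesicles are imaged in
three confocal scans (donor, acceptor, FRET). The bright membrane ring is
detected, the radial intensity profile is fitted as a Gaussian on an
error-function baseline, and the integral A·σ·√(2π) gives the membrane
intensity per unit length. After bleed-through and direct-excitation
correction, the unquenched donor signal is reconstructed by photon
bookkeeping, I_D,corr = I_D + (Q_D/Q_A)·g·F_sens, so that
Eapp = 1 − I_D/I_D,corr, and standard-solution calibration converts
intensities to absolute donor/acceptor densities (molecules/µm²). Per
vesicle the pipeline reports Eapp, σ_D, σ_A and the acceptor fraction
x_a = σ_A/(σ_A+σ_D).

**Intrinsic FRET and the two-state association model.** Vesicles are
binned by total receptor density (≥ 8 per bin) and corrected to

    Intrinsic FRET = (Eapp − E_proximity) / x_a

where E_proximity is the FRET expected from randomly co-localized,
non-interacting receptors (a Monte-Carlo model with an exact closed-form
cross-check). The binned points are fitted either with the mass-action
monomer–dimer model, value(T) = Ẽ·f_dimer(T; K_d), whose plateau Ẽ is the
pairwise FRET efficiency of the dimer, or with a horizontal line for
constitutively dimeric constructs.

**Kinase kinetics.** Initial velocities v(S) = V_max·S/(K_m+S) are fitted
by nonlinear least squares; duplicates are refit separately for parameter
standard deviations; k_cat = V_max/E₀ and the specificity constant
k_cat/K_m are reported, with censored lower bounds when the data show no
curvature and linear-range/turnover diagnostics.

## Worked example

```python
import memfret

# end-to-end vesicle experiment for the TM-only construct:
# 100 synthetic vesicles, detect -> quantify -> correct -> bin -> fit
res = memfret.run_vesicle_study("tm_only", n_vesicles=100, seed=1,
                                model="association")
fit = res.fit
print(f"plateau E~   : {fit.plateau:.3f} +/- {fit.plateau_stderr:.3f}")
print(f"Kd2d (um^-2) : {fit.Kd2d:.0f} +/- {fit.Kd2d_stderr:.0f}")

# live-cell spectral assay, ligand-bound conformation
spec = memfret.run_spectral_study("ecd_tm_liganded", n_pixels=10000, seed=2)
print(f"pixel peak   : {spec.fit.peak:.3f}")

# kinase kinetics of the phosphorylated full-length receptor
kin = memfret.run_kinetics_study("igf1r_fl_phos")
print(f"Km_app {kin['Km_app_uM']:.0f} uM, kcat {kin['kcat_per_min']:.0f} /min")
```

prints

```
plateau E~   : 0.374 +/- 0.005
Kd2d (um^-2) : 139 +/- 15
pixel peak   : 0.340
Km_app 89 uM, kcat 749 /min
```

The plateau is the pairwise dimer FRET efficiency recovered from noisy
images of a construct whose ground truth is Ẽ = 0.38 at K_d = 150 µm⁻²;
the live-cell peak recovers a ground-truth pixel population centred at
0.34; the kinetics refit returns the generator's Michaelis–Menten
parameters exactly on noiseless data.

A command-line interface mirrors the library
(`memfret simulate | vesicles | spectral | dimerfit | kinetics | run`);
e.g.

```bash
memfret simulate --preset tm_only --n-vesicles 40 --seed 1 --out images/
memfret vesicles --images images/ --out vesicles.csv
memfret dimerfit --vesicles vesicles.csv --model auto --out fit.json
```

## Layout

- `memfret.photophysics` — FRET closed forms, Förster radius, proximity model
- `memfret.reference` — synthetic fluorophore reference spectra
- `memfret.synthetic` — scenes, image renders, kinetics data generators
- `memfret.vesicle` — vesicle detection, profile fits, quantitation
- `memfret.spectral` — spectral unmixing, masking, histogram fits
- `memfret.dimer` — intrinsic FRET, binning, association/horizontal fits
- `memfret.kinetics` — Michaelis–Menten fitting and diagnostics
- `memfret.presets`, `memfret.pipeline`, `memfret.io`, `memfret.cli` —
  study presets, orchestration, file formats, CLI

See `docs/methods.md` for the models, corrections, parameter choices and
known limitations.
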