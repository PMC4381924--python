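"""Closed-form FRET photophysics.

Pairwise Förster transfer, Förster radius from spectral overlap, spectrally
resolved and donor-quenching apparent efficiencies, unquenched-donor
reconstruction, and the random-proximity FRET model (Monte Carlo reference
plus an exact Poisson-process closed form).

Unit conventions
----------------
Molecular separations and Förster radii are in ångström (Å); surface
densities are molecules/µm²; box sides are µm. ``A_PER_UM`` converts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import integrate
from scipy.spatial import cKDTree

A_PER_UM = 1e4  # ångström per micrometre


class NoSpectralOverlapError(ValueError):
    """Raised when donor emission and acceptor extinction share no support."""


class UndefinedPixelError(ValueError):
    """Raised when a pixel carries no usable signal (caller should mask it)."""


# ---------------------------------------------------------------------------
# Spectra and fluorophore pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectrum on a strictly increasing wavelength grid (nm)."""

    wavelengths: NDArray[np.float64]
    values: NDArray[np.float64]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        va = np.asarray(self.values, dtype=float)
        if wl.shape != va.shape or wl.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(va < 0):
            raise ValueError("spectral values must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", va)

    def integral(self) -> float:
        """Trapezoidal integral over the grid (value units × nm)."""
        return float(np.trapezoid(self.values, self.wavelengths))

    def peak_normalized(self) -> "Spectrum":
        peak = float(self.values.max())
        if peak <= 0:
            raise ValueError("cannot peak-normalize an all-zero spectrum")
        return Spectrum(self.wavelengths, self.values / peak)

    def interpolate(self, grid: ArrayLike) -> NDArray[np.float64]:
        """Linear interpolation onto ``grid``, zero outside support."""
        return np.interp(np.asarray(grid, dtype=float), self.wavelengths,
                         self.values, left=0.0, right=0.0)

    def to_csv(self, path: str | Path, value_name: str = "value") -> None:
        arr = np.column_stack([self.wavelengths, self.values])
        header = f"wavelength_nm,{value_name}"
        np.savetxt(path, arr, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Spectrum":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(arr[:, 0], arr[:, 1])


@dataclass(frozen=True)
class BleedthroughCoefficients:
    """Spectral contamination of the FRET channel.

    ``donor_into_fret`` — fraction of the donor-channel signal appearing in
    the FRET channel (donor emission tail). ``acceptor_direct_excitation`` —
    fraction of the acceptor-channel signal appearing in the FRET channel
    (direct acceptor excitation at the donor line).
    """

    donor_into_fret: float = 0.0
    acceptor_direct_excitation: float = 0.0

    def __post_init__(self) -> None:
        for name in ("donor_into_fret", "acceptor_direct_excitation"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")


@dataclass(frozen=True)
class FluorophorePair:
    """Photophysical constants shared by all FRET arithmetic.

    Reference emission spectra are stored unit-peak normalized so that the
    spectral unmixing amplitudes are maximum emission intensities. ``w_D`` /
    ``w_A`` are the integrals of the stored emission spectra (nm) and must
    match them; ``R0`` is the Förster radius in Å.
    """

    donor_name: str
    acceptor_name: str
    Q_D: float
    Q_A: float
    donor_emission: Spectrum
    acceptor_emission: Spectrum
    acceptor_extinction: Spectrum
    w_D: float
    w_A: float
    R0: float
    bleedthrough: BleedthroughCoefficients = field(
        default_factory=BleedthroughCoefficients)

    def __post_init__(self) -> None:
        for name in ("Q_D", "Q_A"):
            q = getattr(self, name)
            if not 0.0 < q <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {q}")
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")
        for name, w, spec in (("w_D", self.w_D, self.donor_emission),
                              ("w_A", self.w_A, self.acceptor_emission)):
            if w <= 0:
                raise ValueError(f"{name} must be positive")
            ref = spec.integral()
            if abs(w - ref) > 1e-6 * max(ref, 1.0):
                raise ValueError(
                    f"{name}={w} does not match the spectrum integral {ref}")

    @classmethod
    def from_spectra(cls, donor_name: str, acceptor_name: str, Q_D: float,
                     Q_A: float, donor_emission: Spectrum,
                     acceptor_emission: Spectrum,
                     acceptor_extinction: Spectrum,
                     bleedthrough: BleedthroughCoefficients | None = None,
                     kappa2: float = 2.0 / 3.0,
                     n_refr: float = 1.33) -> "FluorophorePair":
        """Build a pair: peak-normalize emissions, derive w's and R0."""
        dem = donor_emission.peak_normalized()
        aem = acceptor_emission.peak_normalized()
        r0 = forster_radius(dem, acceptor_extinction, Q_D, kappa2=kappa2,
                            n_refr=n_refr)
        return cls(donor_name=donor_name, acceptor_name=acceptor_name,
                   Q_D=Q_D, Q_A=Q_A, donor_emission=dem,
                   acceptor_emission=aem,
                   acceptor_extinction=acceptor_extinction,
                   w_D=dem.integral(), w_A=aem.integral(), R0=r0,
                   bleedthrough=bleedthrough or BleedthroughCoefficients())

    def to_json(self, path: str | Path) -> None:
        doc = {
            "donor_name": self.donor_name,
            "acceptor_name": self.acceptor_name,
            "Q_D": self.Q_D,
            "Q_A": self.Q_A,
            "w_D": self.w_D,
            "w_A": self.w_A,
            "R0": self.R0,
            "bleedthrough": {
                "donor_into_fret": self.bleedthrough.donor_into_fret,
                "acceptor_direct_excitation":
                    self.bleedthrough.acceptor_direct_excitation,
            },
            "donor_emission": {
                "wavelengths": self.donor_emission.wavelengths.tolist(),
                "values": self.donor_emission.values.tolist(),
            },
            "acceptor_emission": {
                "wavelengths": self.acceptor_emission.wavelengths.tolist(),
                "values": self.acceptor_emission.values.tolist(),
            },
            "acceptor_extinction": {
                "wavelengths": self.acceptor_extinction.wavelengths.tolist(),
                "values": self.acceptor_extinction.values.tolist(),
            },
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "FluorophorePair":
        doc = json.loads(Path(path).read_text())
        return cls(
            donor_name=doc["donor_name"], acceptor_name=doc["acceptor_name"],
            Q_D=doc["Q_D"], Q_A=doc["Q_A"],
            donor_emission=Spectrum(**doc["donor_emission"]),
            acceptor_emission=Spectrum(**doc["acceptor_emission"]),
            acceptor_extinction=Spectrum(**doc["acceptor_extinction"]),
            w_D=doc["w_D"], w_A=doc["w_A"], R0=doc["R0"],
            bleedthrough=BleedthroughCoefficients(**doc["bleedthrough"]))


@dataclass(frozen=True)
class SpectralUnmixResult:
    """Donor/acceptor amplitudes of one pixel spectrum (counts at peak)."""

    k_DA: float
    k_AD: float
    residual_rss: float = 0.0

    def __post_init__(self) -> None:
        if self.k_DA < 0 or self.k_AD < 0:
            raise ValueError("unmixed amplitudes must be non-negative")


@dataclass(frozen=True)
class ProximityEstimate:
    """Random-proximity FRET at given donor/acceptor surface densities."""

    E_proximity: float
    mc_stderr: float
    sigma_D: float
    sigma_A: float
    r_exclusion: float
    n_realizations: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.E_proximity < 1.0:
            raise ValueError("E_proximity must lie in [0, 1)")
        if self.mc_stderr < 0:
            raise ValueError("mc_stderr must be non-negative")


# ---------------------------------------------------------------------------
# Closed-form efficiencies
# ---------------------------------------------------------------------------


def pairwise_efficiency(r: ArrayLike, R0: float) -> NDArray[np.float64] | float:
    """Förster transfer efficiency 1/(1 + (r/R0)^6) for separation r (Å)."""
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("separation must be non-negative")
    out = 1.0 / (1.0 + (r_arr / R0) ** 6)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def separation_for_efficiency(E: float, R0: float) -> float:
    """Inverse of :func:`pairwise_efficiency`: separation giving E (Å)."""
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    if not 0.0 < E <= 1.0:
        raise ValueError("E must lie in (0, 1]")
    if E == 1.0:
        return 0.0
    return R0 * ((1.0 - E) / E) ** (1.0 / 6.0)


def overlap_integral(donor_emission: Spectrum,
                     acceptor_extinction: Spectrum) -> float:
    """Overlap integral J = ∫f_D ε_A λ⁴ dλ / ∫f_D dλ (M⁻¹cm⁻¹nm⁴).

    Evaluated trapezoidally on the union grid restricted to the common
    wavelength window; raises :class:`NoSpectralOverlapError` when the
    product vanishes everywhere.
    """
    lo = max(donor_emission.wavelengths[0], acceptor_extinction.wavelengths[0])
    hi = min(donor_emission.wavelengths[-1],
             acceptor_extinction.wavelengths[-1])
    if hi <= lo:
        raise NoSpectralOverlapError(
            "donor emission and acceptor extinction do not overlap")
    grid = np.union1d(donor_emission.wavelengths,
                      acceptor_extinction.wavelengths)
    grid = grid[(grid >= lo) & (grid <= hi)]
    f_d = donor_emission.interpolate(grid)
    eps = acceptor_extinction.interpolate(grid)
    num = np.trapezoid(f_d * eps * grid ** 4, grid)
    den = donor_emission.integral()
    if num <= 0:
        raise NoSpectralOverlapError("spectral overlap product is zero")
    return float(num / den)


def forster_radius(donor_emission: Spectrum, acceptor_extinction: Spectrum,
                   Q_D: float, kappa2: float = 2.0 / 3.0,
                   n_refr: float = 1.33) -> float:
    """Förster radius R0 = 0.211·(κ² n⁻⁴ Q_D J)^(1/6) in Å.

    J is in M⁻¹cm⁻¹nm⁴. Defaults κ²=2/3 and n=1.33 describe freely rotating
    fluorophores in an aqueous environment.
    """
    if not 0.0 < Q_D <= 1.0:
        raise ValueError("Q_D must be in (0, 1]")
    if kappa2 <= 0:
        raise ValueError("kappa2 must be positive")
    if n_refr <= 0:
        raise ValueError("refractive index must be positive")
    J = overlap_integral(donor_emission, acceptor_extinction)
    return 0.211 * (kappa2 * n_refr ** -4 * Q_D * J) ** (1.0 / 6.0)


def apparent_efficiency_spectral(unmix: SpectralUnmixResult,
                                 pair: FluorophorePair) -> float:
    """Apparent FRET efficiency from spectral unmixing amplitudes.

    Eapp = [1 + (Q_A/Q_D)·(k^DA/k^AD)·(w^D/w^A)]⁻¹ — the photon-bookkeeping
    form: donor photons scale as Q_D(1−E)·w_D, sensitized acceptor photons
    as Q_A·E·w_A, with the amplitudes k measured at the emission peaks of
    unit-peak reference spectra.
    """
    k_da, k_ad = unmix.k_DA, unmix.k_AD
    if k_da == 0.0 and k_ad == 0.0:
        raise UndefinedPixelError("both unmixed amplitudes are zero")
    if k_ad == 0.0:
        return 0.0
    if k_da == 0.0:
        return 1.0
    ratio = (pair.Q_A / pair.Q_D) * (k_da / k_ad) * (pair.w_D / pair.w_A)
    return 1.0 / (1.0 + ratio)


def donor_quenching_efficiency(I_Dm: float, I_Dcorr: float) -> float:
    """Eapp = 1 − I_Dm/I_Dcorr from quenched vs unquenched donor intensity.

    Values slightly outside [0, 1] from measurement noise are returned as-is
    (downstream fits stay unbiased); callers flag them.
    """
    if I_Dcorr <= 0:
        raise ValueError("unquenched donor intensity must be positive")
    return 1.0 - I_Dm / I_Dcorr


def reconstruct_unquenched_donor(I_Dm: float, F_sens: float,
                                 pair: FluorophorePair,
                                 gain_ratio: float = 1.0) -> float:
    """Unquenched donor intensity from energy conservation.

    Every photon the acceptor emits by sensitized emission corresponds to a
    donor photon lost to transfer, re-scaled by the quantum-yield ratio and
    the donor/acceptor detection-efficiency ratio:
    I_D,corr = I_Dm + (Q_D/Q_A)·gain_ratio·F_sens.
    """
    if I_Dm < 0 or F_sens < 0:
        raise ValueError("intensities must be non-negative")
    if gain_ratio <= 0:
        raise ValueError("gain_ratio must be positive")
    return I_Dm + (pair.Q_D / pair.Q_A) * gain_ratio * F_sens


# ---------------------------------------------------------------------------
# Random-proximity FRET
# ---------------------------------------------------------------------------

DEFAULT_R_EXCLUSION = 55.0
"""Default donor–acceptor hard-core exclusion radius (Å).

Two fluorescent-protein-tagged receptors at physical contact hold their
fluorophores roughly one β-barrel-plus-linker apart — comparable to the
intra-dimer fluorophore separation (~58 Å for a dimer with Ẽ≈0.38 at
R0≈53 Å) — so unbound neighbours cannot approach much closer than ~55 Å.
"""


def _min_image(delta: NDArray[np.float64], box: float) -> NDArray[np.float64]:
    return delta - box * np.round(delta / box)


def donor_transfer_sums(donor_xy: NDArray[np.float64],
                        acceptor_xy: NDArray[np.float64], R0_um: float,
                        box_side: float | None = None,
                        cutoff_factor: float = 8.0) -> NDArray[np.float64]:
    """Per-donor transfer-rate sums S_i = Σ_j (R0/r_ij)^6 (lengths in µm).

    With ``box_side`` set, distances use the minimum-image convention on a
    periodic square box. Pairs beyond ``cutoff_factor·R0`` contribute
    negligibly ((1/8)^6 ≈ 4e-6) and are skipped via a KD-tree query.
    """
    n_d = len(donor_xy)
    S = np.zeros(n_d)
    if len(acceptor_xy) == 0 or n_d == 0:
        return S
    cutoff = cutoff_factor * R0_um
    if box_side is not None and cutoff * 2 >= box_side:
        # box too small for tree pruning: brute force with minimum image
        d = donor_xy[:, None, :] - acceptor_xy[None, :, :]
        d = _min_image(d, box_side)
        r2 = np.einsum("ijk,ijk->ij", d, d)
        r2 = np.maximum(r2, 1e-24)
        return ((R0_um ** 2 / r2) ** 3).sum(axis=1)
    tree = cKDTree(acceptor_xy, boxsize=box_side)
    pairs = tree.query_ball_point(donor_xy, cutoff)
    for i, idx in enumerate(pairs):
        if not idx:
            continue
        d = acceptor_xy[idx] - donor_xy[i]
        if box_side is not None:
            d = _min_image(d, box_side)
        r2 = np.maximum((d ** 2).sum(axis=1), 1e-24)
        S[i] = ((R0_um ** 2 / r2) ** 3).sum()
    return S


def proximity_fret_mc(sigma_D: float, sigma_A: float, R0: float,
                      r_exclusion: float = DEFAULT_R_EXCLUSION,
                      box_side: float | None = None,
                      n_realizations: int = 100,
                      seed: int | np.random.Generator = 0,
                      p_partner: float = 0.0,
                      E_partner: float = 0.0) -> ProximityEstimate:
    """Monte-Carlo random-proximity FRET on a periodic membrane patch.

    Donors and acceptors are Poisson-distributed at the given surface
    densities (µm⁻²); acceptor placements within ``r_exclusion`` (Å) of any
    donor are re-drawn (hard-core exclusion). Per donor,
    E_i = S_i/(1+S_i) with S_i the pairwise rate sum; the estimate averages
    over donors and realizations. Donors do not transfer to donors, so the
    result does not depend on ``sigma_D`` beyond sampling noise.

    With ``p_partner`` > 0 the estimate is the *nonspecific contribution*
    for a mixed population in which a fraction ``p_partner`` of donors also
    hold a specific acceptor partner of pairwise efficiency ``E_partner``:
    because transfer rates compete, a random neighbour raises a dimerized
    donor's efficiency by less than a monomer's, so the population's
    proximity contribution is

        p·(E[(S_p+S)/(1+S_p+S)] − E_partner) + (1−p)·E[S/(1+S)],

    with S_p = E_partner/(1−E_partner). ``p_partner = 0`` reduces exactly
    to the monomer expression.
    """
    if sigma_D < 0 or sigma_A < 0:
        raise ValueError("densities must be non-negative")
    if n_realizations < 1:
        raise ValueError("need at least one realization")
    if not 0.0 <= p_partner <= 1.0:
        raise ValueError("p_partner must be in [0, 1]")
    if not 0.0 <= E_partner < 1.0:
        raise ValueError("E_partner must be in [0, 1)")
    s_partner = E_partner / (1.0 - E_partner)
    r0_um = R0 / A_PER_UM
    rex_um = r_exclusion / A_PER_UM
    if box_side is None:
        box_side = max(50.0 * r0_um, 0.3)
    if box_side < 50.0 * r0_um:
        raise ValueError("box_side must be at least 50·R0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    area = box_side ** 2
    realization_means = []
    for _ in range(n_realizations):
        n_d = rng.poisson(sigma_D * area)
        n_a = rng.poisson(sigma_A * area)
        if n_d == 0:
            continue
        donors = rng.uniform(0.0, box_side, size=(n_d, 2))
        acceptors = rng.uniform(0.0, box_side, size=(n_a, 2))
        if n_a and rex_um > 0:
            tree = cKDTree(donors, boxsize=box_side)
            for _attempt in range(200):
                bad = np.array([len(v) > 0 for v in tree.query_ball_point(
                    acceptors, rex_um)])
                if not bad.any():
                    break
                acceptors[bad] = rng.uniform(0.0, box_side,
                                             size=(int(bad.sum()), 2))
            else:
                raise RuntimeError(
                    "could not place acceptors outside the exclusion zones; "
                    "density too high for the exclusion radius")
        S = donor_transfer_sums(donors, acceptors, r0_um, box_side=box_side)
        e_mono = float(np.mean(S / (1.0 + S)))
        if p_partner > 0.0:
            e_dim = float(np.mean((s_partner + S)
                                  / (1.0 + s_partner + S)))
            realization_means.append(p_partner * (e_dim - E_partner)
                                     + (1.0 - p_partner) * e_mono)
        else:
            realization_means.append(e_mono)
    if not realization_means:
        raise ValueError("no donors were placed in any realization")
    means = np.asarray(realization_means)
    e = float(means.mean())
    stderr = (float(means.std(ddof=1) / np.sqrt(len(means)))
              if len(means) > 1 else 0.0)
    return ProximityEstimate(E_proximity=min(e, np.nextafter(1.0, 0.0)),
                             mc_stderr=stderr, sigma_D=sigma_D,
                             sigma_A=sigma_A, r_exclusion=r_exclusion,
                             n_realizations=n_realizations)


def proximity_fret_low_density(sigma_A: float, R0: float,
                               r_exclusion: float = DEFAULT_R_EXCLUSION,
                               max_reduced_density: float = 0.2) -> float:
    """Closed-form random-proximity FRET for Poisson-distributed acceptors.

    Exact for the same model as :func:`proximity_fret_mc` (rate additivity,
    hard-core exclusion, infinite plane): writing the donor's relative
    fluorescence 1/(1+S) = ∫₀^∞ e^{−(1+S)τ}dτ and taking the Poisson
    expectation over acceptor configurations,

        E = 1 − ∫₀^∞ e^{−τ} exp(−σ_A ∫_{r_ex}^∞ (1−e^{−τ(R0/r)^6}) 2πr dr) dτ.

    Its small-density limit is the first-order expression
    σ_A ∫ E_pair(r)·2πr dr. Restricted to reduced densities
    σ_A·π·R0² ≤ ``max_reduced_density`` to mirror the Monte-Carlo validity
    checks of callers, although the formula itself holds at any density.
    """
    if sigma_A < 0:
        raise ValueError("sigma_A must be non-negative")
    if sigma_A == 0.0:
        return 0.0
    r0_um = R0 / A_PER_UM
    rex_um = r_exclusion / A_PER_UM
    reduced = sigma_A * np.pi * r0_um ** 2
    if reduced > max_reduced_density:
        raise ValueError(
            f"reduced density {reduced:.3g} above validity window "
            f"{max_reduced_density}")

    def inner(tau: float) -> float:
        # ∫ (1−exp(−τ (R0/r)^6)) 2πr dr from r_ex to ∞, in µm²
        def g(r):
            return (1.0 - np.exp(-tau * (r0_um / r) ** 6)) * 2.0 * np.pi * r

        hi = 60.0 * r0_um
        val, _ = integrate.quad(g, rex_um, hi, limit=200)
        # analytic tail: 1−e^{−x} ≈ x for r > hi
        tail = tau * 2.0 * np.pi * r0_um ** 6 / (4.0 * hi ** 4)
        return val + tail

    def outer(tau: float) -> float:
        return np.exp(-tau) * np.exp(-sigma_A * inner(tau))

    surv, _ = integrate.quad(outer, 0.0, 60.0, limit=200)
    return float(1.0 - surv)
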