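"""Ground-truth generators: membrane scenes, rendered images, kinetics data.

A :class:`MembraneScene` is a 2-D molecular configuration on a periodic
rectangular membrane patch obeying a monomer–dimer mass-action equilibrium.
For vesicle imaging the patch is the equatorial strip of the vesicle
(length = circumference, height = optical-section height) wrapped onto the
bright ring of the image. Renders follow the three-scan confocal protocol
(donor / acceptor / FRET scans) with Gaussian membrane profiles on an
error-function baseline, Poisson shot noise, Gaussian read noise, donor
bleed-through and direct acceptor excitation. A separate renderer produces
per-pixel emission spectra (450–600 nm) consistent with a ground-truth
apparent-efficiency field, and a Michaelis–Menten generator produces
initial-velocity tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import norm

from .photophysics import (A_PER_UM, DEFAULT_R_EXCLUSION, FluorophorePair,
                           separation_for_efficiency)

DONOR, ACCEPTOR, DARK = 0, 1, 2


# ---------------------------------------------------------------------------
# Monomer–dimer equilibrium
# ---------------------------------------------------------------------------


def solve_dimer_equilibrium(total_density: float,
                            Kd2d: float) -> tuple[float, float, float]:
    """Unique non-negative root of the 2-D mass-action monomer–dimer model.

    With monomer density M, dimer density D, dissociation constant
    Kd2d = M²/D (molecules/µm²) and conservation T = M + 2D, returns
    ``(M, D, dimer_fraction)`` where dimer_fraction = 2D/T is the fraction
    of molecules residing in dimers.
    """
    if total_density < 0:
        raise ValueError("total_density must be non-negative")
    if Kd2d <= 0:
        raise ValueError("Kd2d must be positive")
    T = float(total_density)
    if T == 0.0:
        return 0.0, 0.0, 0.0
    # root of 2M²/Kd + M − T = 0, in the cancellation-free form
    M = 2.0 * T / (1.0 + np.sqrt(1.0 + 8.0 * T / Kd2d))
    D = M * M / Kd2d
    return float(M), float(D), float(2.0 * D / T)


def dimer_fraction(total_density, Kd2d: float):
    """Vectorized dimer fraction 2D/T of the mass-action model."""
    T = np.asarray(total_density, dtype=float)
    Tp = np.maximum(T, 0.0)
    M = 2.0 * Tp / (1.0 + np.sqrt(1.0 + 8.0 * Tp / Kd2d))
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(T > 0, 2.0 * M * M / Kd2d / np.where(T > 0, T, 1.0),
                        0.0)
    return frac if frac.ndim else float(frac)


# ---------------------------------------------------------------------------
# Scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneParams:
    """Ground-truth parameters of one membrane scene.

    Exactly one of ``E_dimer`` (pairwise FRET efficiency of a donor–acceptor
    dimer) or ``intra_dimer_separation`` (Å) must be given; the other is
    derived through the Förster relation at render time.
    """

    total_density: float  # receptors/µm²
    x_a_true: float  # acceptor labeling fraction
    Kd2d: float  # molecules/µm²
    E_dimer: float | None = None
    intra_dimer_separation: float | None = None  # Å
    dark_fraction: float = 0.0
    area: float = 25.0  # µm²
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_density < 0 or self.Kd2d <= 0 or self.area <= 0:
            raise ValueError("densities/area must be non-negative, Kd2d > 0")
        if not 0.0 <= self.x_a_true <= 1.0:
            raise ValueError("x_a_true must be in [0, 1]")
        if not 0.0 <= self.dark_fraction < 1.0:
            raise ValueError("dark_fraction must be in [0, 1)")
        if (self.E_dimer is None) == (self.intra_dimer_separation is None):
            raise ValueError(
                "set exactly one of E_dimer / intra_dimer_separation")
        if self.E_dimer is not None and not 0.0 <= self.E_dimer <= 1.0:
            raise ValueError("E_dimer must be in [0, 1]")

    def separation(self, R0: float | None = None) -> float:
        """Intra-dimer fluorophore separation in Å."""
        if self.intra_dimer_separation is not None:
            return self.intra_dimer_separation
        if R0 is None:
            raise ValueError("R0 required to convert E_dimer to a separation")
        if self.E_dimer == 0.0:
            return np.inf
        return separation_for_efficiency(self.E_dimer, R0)


@dataclass(frozen=True)
class MembraneScene:
    """Realized molecular configuration on a periodic rectangular patch."""

    positions: NDArray[np.float64]  # (N, 2) µm, within extent
    labels: NDArray[np.int64]  # DONOR / ACCEPTOR / DARK
    oligomer_ids: NDArray[np.int64]  # shared by dimer partners
    extent: tuple[float, float]  # (Lx, Ly) µm, periodic
    params: SceneParams

    @property
    def area(self) -> float:
        return self.extent[0] * self.extent[1]

    @property
    def sigma_D(self) -> float:
        """Realized visible donor surface density (µm⁻²)."""
        return float(np.sum(self.labels == DONOR)) / self.area

    @property
    def sigma_A(self) -> float:
        return float(np.sum(self.labels == ACCEPTOR)) / self.area

    @property
    def realized_dimer_fraction(self) -> float:
        if len(self.oligomer_ids) == 0:
            return 0.0
        _, counts = np.unique(self.oligomer_ids, return_counts=True)
        return float((counts == 2).sum() * 2 / len(self.oligomer_ids))


def generate_scene(params: SceneParams, R0: float | None = None,
                   extent: tuple[float, float] | None = None) -> MembraneScene:
    """Draw one membrane scene from the mass-action equilibrium.

    Molecule counts are Poisson at the equilibrium monomer/dimer densities;
    each molecule is labeled acceptor with probability ``x_a_true`` else
    donor, then dark with probability ``dark_fraction`` (independently).
    Dimer partners sit at the configured separation in a uniformly random
    orientation; the patch is periodic in both directions.
    """
    rng = np.random.default_rng(params.seed)
    if extent is None:
        side = float(np.sqrt(params.area))
        extent = (side, side)
    lx, ly = extent
    if abs(lx * ly - params.area) > 1e-9 * params.area:
        raise ValueError("extent is inconsistent with params.area")
    M, D, _ = solve_dimer_equilibrium(params.total_density, params.Kd2d)
    n_mono = rng.poisson(M * params.area)
    n_dim = rng.poisson(D * params.area)
    sep_um = params.separation(R0) / A_PER_UM if (n_dim > 0) else 0.0
    if not np.isfinite(sep_um):
        raise ValueError("E_dimer = 0 gives an unbounded dimer separation")

    mono_xy = rng.uniform((0, 0), (lx, ly), size=(n_mono, 2))
    centers = rng.uniform((0, 0), (lx, ly), size=(n_dim, 2))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_dim)
    half = 0.5 * sep_um * np.column_stack([np.cos(phi), np.sin(phi)])
    dim_a = centers + half
    dim_b = centers - half
    positions = np.concatenate([mono_xy, dim_a, dim_b], axis=0)
    positions = np.mod(positions, (lx, ly))

    oligomer_ids = np.concatenate([
        np.arange(n_mono),
        n_mono + np.arange(n_dim),
        n_mono + np.arange(n_dim),
    ]).astype(np.int64)

    n_total = n_mono + 2 * n_dim
    labels = np.where(rng.uniform(size=n_total) < params.x_a_true,
                      ACCEPTOR, DONOR).astype(np.int64)
    labels[rng.uniform(size=n_total) < params.dark_fraction] = DARK
    return MembraneScene(positions=positions, labels=labels,
                         oligomer_ids=oligomer_ids, extent=(lx, ly),
                         params=params)


def scene_donor_efficiencies(scene: MembraneScene, R0: float,
                             r_exclusion: float = DEFAULT_R_EXCLUSION,
                             include_proximity: bool = True,
                             cutoff_factor: float = 8.0
                             ) -> NDArray[np.float64]:
    """Per-donor FRET efficiency of the scene, rate-additive.

    Each donor transfers to its dimer partner (if that partner carries a
    visible acceptor) and, when ``include_proximity`` is on, to every
    unrelated acceptor beyond the hard-core exclusion radius:
    E_i = S_i/(1+S_i), S_i = Σ_j (R0/r_ij)^6 with minimum-image distances.
    Non-partner pairs closer than ``r_exclusion`` are treated as excluded
    volume and skipped (two tagged receptors cannot interpenetrate).
    """
    donors = np.flatnonzero(scene.labels == DONOR)
    acceptors = np.flatnonzero(scene.labels == ACCEPTOR)
    S = np.zeros(len(donors))
    if len(donors) == 0:
        return S
    r0_um = R0 / A_PER_UM
    rex_um = r_exclusion / A_PER_UM
    if len(acceptors) > 0 and include_proximity:
        box = np.array(scene.extent)
        tree_d = cKDTree(scene.positions[donors], boxsize=box)
        tree_a = cKDTree(scene.positions[acceptors], boxsize=box)
        cutoff = min(cutoff_factor * r0_um, 0.45 * float(box.min()))
        mat = tree_d.sparse_distance_matrix(tree_a, cutoff,
                                            output_type="coo_matrix")
        if mat.nnz:
            same = (scene.oligomer_ids[donors][mat.row]
                    == scene.oligomer_ids[acceptors][mat.col])
            keep = (~same) & (mat.data >= rex_um) & (mat.data > 0)
            contrib = (r0_um / mat.data[keep]) ** 6
            np.add.at(S, mat.row[keep], contrib)
    # intra-dimer partner term, independent of the proximity switch
    if len(acceptors) > 0:
        olig = scene.oligomer_ids
        order = np.argsort(olig, kind="stable")
        so = olig[order]
        partner = np.full(len(olig), -1, dtype=np.int64)
        adjacent = np.flatnonzero(so[:-1] == so[1:])  # dimer pairs
        partner[order[adjacent]] = order[adjacent + 1]
        partner[order[adjacent + 1]] = order[adjacent]
        p = partner[donors]
        has_acc_partner = (p >= 0) & (scene.labels[np.maximum(p, 0)]
                                      == ACCEPTOR)
        sep_um = scene.params.separation(R0) / A_PER_UM
        s_partner = (r0_um / sep_um) ** 6 if sep_um > 0 else np.inf
        S[has_acc_partner] += s_partner
    with np.errstate(over="ignore"):
        return np.where(np.isinf(S), 1.0, S / (1.0 + S))


# ---------------------------------------------------------------------------
# Vesicle image rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticsParams:
    """Imaging geometry and detection parameters for vesicle renders.

    Gains are counts per emitted-photon-equivalent and channel: a donor
    contributes ``gain_donor·Q_D·(1−E)`` counts to the donor scan and
    ``gain_fret·Q_A·E`` sensitized counts to the FRET scan; an acceptor
    contributes ``gain_acceptor·Q_A`` counts to the acceptor scan.
    Backgrounds are counts/pixel (interior, exterior) shared by channels.
    """

    pixel_size: float = 0.1  # µm
    image_shape: tuple[int, int] = (128, 128)
    membrane_psf_sigma: float = 0.2  # µm
    baseline_sigma: float = 0.2  # µm, erf step width
    vesicle_radius: float = 3.0  # µm
    vesicle_center: tuple[float, float] | None = None  # pixel coords (x, y)
    section_height: float = 1.0  # µm of membrane seen in the equatorial ring
    gain_donor: float = 40.0
    gain_fret: float = 40.0
    gain_acceptor: float = 40.0
    background_interior: float = 6.0
    background_exterior: float = 2.0
    read_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if min(self.pixel_size, self.vesicle_radius, self.gain_donor,
               self.gain_fret, self.gain_acceptor,
               self.membrane_psf_sigma) <= 0:
            raise ValueError("pixel size, radius, psf and gains must be > 0")

    @property
    def gain_ratio(self) -> float:
        """Donor/acceptor detection-efficiency ratio used in reconstruction."""
        return self.gain_donor / self.gain_fret

    @property
    def circumference(self) -> float:
        return 2.0 * np.pi * self.vesicle_radius

    @property
    def strip_extent(self) -> tuple[float, float]:
        return (self.circumference, self.section_height)

    @property
    def strip_area(self) -> float:
        return self.circumference * self.section_height

    def center_px(self) -> tuple[float, float]:
        if self.vesicle_center is not None:
            return self.vesicle_center
        ny, nx = self.image_shape
        return ((nx - 1) / 2.0, (ny - 1) / 2.0)


@dataclass(frozen=True)
class VesicleGroundTruth:
    """What the generator knows about one rendered vesicle."""

    mean_Eapp: float  # donor-averaged transfer efficiency
    sigma_D: float  # visible donors/µm²
    sigma_A: float
    dimer_fraction: float
    scene_params: SceneParams


@dataclass(frozen=True)
class VesicleImageSet:
    """The three co-registered confocal scans of one vesicle field."""

    donor_scan: NDArray[np.float64]
    acceptor_scan: NDArray[np.float64]
    fret_scan: NDArray[np.float64]
    optics: OpticsParams
    pair: FluorophorePair
    ground_truth: VesicleGroundTruth | None = None

    def __post_init__(self) -> None:
        if not (self.donor_scan.shape == self.acceptor_scan.shape
                == self.fret_scan.shape):
            raise ValueError("the three scans must share dimensions")

    @property
    def channels(self) -> dict[str, NDArray[np.float64]]:
        return {"donor": self.donor_scan, "acceptor": self.acceptor_scan,
                "fret": self.fret_scan}


def scene_for_vesicle(params: SceneParams, optics: OpticsParams,
                      R0: float | None = None) -> MembraneScene:
    """Scene on the equatorial strip of a vesicle (area = 2πR·h)."""
    strip = replace(params, area=optics.strip_area)
    return generate_scene(strip, R0=R0, extent=optics.strip_extent)


def render_vesicle_images(scene: MembraneScene, optics: OpticsParams,
                          pair: FluorophorePair,
                          seed: int | np.random.Generator = 0,
                          noise: bool = True,
                          include_proximity: bool = True,
                          r_exclusion: float = DEFAULT_R_EXCLUSION,
                          n_angle_bins: int = 720) -> VesicleImageSet:
    """Render the donor/acceptor/FRET confocal scans of one vesicle.

    The scene strip is wrapped onto the equatorial circle; the radial
    intensity profile is a Gaussian of the membrane PSF width on an
    error-function baseline stepping from the interior to the exterior
    background. The FRET scan carries sensitized emission plus donor
    bleed-through plus directly excited acceptor signal.
    """
    lx, ly = scene.extent
    if abs(lx - optics.circumference) > 1e-6 * optics.circumference:
        raise ValueError("scene extent does not match the vesicle "
                         "circumference; use scene_for_vesicle()")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    donors = scene.labels == DONOR
    accs = scene.labels == ACCEPTOR
    E = scene_donor_efficiencies(scene, pair.R0, r_exclusion=r_exclusion,
                                 include_proximity=include_proximity)

    # per-molecule counts in each physical channel
    d_counts = optics.gain_donor * pair.Q_D * (1.0 - E)  # donors
    sens_counts = optics.gain_fret * pair.Q_A * E  # donors
    a_counts = np.full(int(accs.sum()), optics.gain_acceptor * pair.Q_A)

    bt = pair.bleedthrough
    theta_mol = scene.positions[:, 0] / optics.vesicle_radius  # radians
    bins = np.floor(theta_mol / (2.0 * np.pi) * n_angle_bins).astype(int)
    bins = np.clip(bins, 0, n_angle_bins - 1)

    def per_angle(mask: NDArray[np.bool_], weights: NDArray[np.float64]):
        return np.bincount(bins[mask], weights=weights,
                           minlength=n_angle_bins)

    amp_donor = per_angle(donors, d_counts)
    amp_sens = per_angle(donors, sens_counts)
    amp_acc = per_angle(accs, a_counts)
    amp_fret = (amp_sens + bt.donor_into_fret * amp_donor
                + bt.acceptor_direct_excitation * amp_acc)

    arc = optics.circumference / n_angle_bins  # µm per angular bin
    # the PSF blurs tangentially as well as radially: circular convolution
    # of the per-angle amplitude with the same Gaussian width
    sigma_bins = optics.membrane_psf_sigma / arc
    lam = {name: ndimage.gaussian_filter1d(amp / arc, sigma_bins,
                                           mode="wrap")
           for name, amp in (("donor", amp_donor), ("acceptor", amp_acc),
                             ("fret", amp_fret))}

    ny, nx = optics.image_shape
    cx, cy = optics.center_px()
    yy, xx = np.mgrid[0:ny, 0:nx]
    dx = (xx - cx) * optics.pixel_size
    dy = (yy - cy) * optics.pixel_size
    d = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    tbin = np.clip((theta / (2.0 * np.pi) * n_angle_bins).astype(int), 0,
                   n_angle_bins - 1)
    sig = optics.membrane_psf_sigma
    gauss = np.exp(-0.5 * ((d - optics.vesicle_radius) / sig) ** 2) / (
        sig * np.sqrt(2.0 * np.pi))
    bg = optics.background_interior + (
        optics.background_exterior - optics.background_interior) * norm.cdf(
        (d - optics.vesicle_radius) / optics.baseline_sigma)

    p2 = optics.pixel_size ** 2
    images = {}
    for name in ("donor", "acceptor", "fret"):
        img = lam[name][tbin] * gauss * p2 + bg
        if noise:
            img = rng.poisson(np.maximum(img, 0.0)).astype(float)
            img += rng.normal(0.0, optics.read_noise_sd, size=img.shape)
        images[name] = img

    n_don = int(donors.sum())
    gt = VesicleGroundTruth(
        mean_Eapp=float(E[~np.isnan(E)].mean()) if n_don else 0.0,
        sigma_D=scene.sigma_D, sigma_A=scene.sigma_A,
        dimer_fraction=scene.realized_dimer_fraction,
        scene_params=scene.params)
    return VesicleImageSet(donor_scan=images["donor"],
                           acceptor_scan=images["acceptor"],
                           fret_scan=images["fret"], optics=optics,
                           pair=pair, ground_truth=gt)


# ---------------------------------------------------------------------------
# Spectral image rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectralImage:
    """An (λ, y, x) spectral stack with optional ground truth."""

    stack: NDArray[np.float64]
    wavelengths: NDArray[np.float64]
    excitation: str = "800nm"
    ground_truth_eapp: NDArray[np.float64] | None = None
    true_membrane_mask: NDArray[np.bool_] | None = None

    def __post_init__(self) -> None:
        if self.stack.ndim != 3:
            raise ValueError("stack must be (wavelength, y, x)")
        if self.stack.shape[0] != len(self.wavelengths):
            raise ValueError("wavelength planes do not match the grid")


def spectral_amplitudes(Eapp, total_counts, pair: FluorophorePair):
    """Donor/acceptor amplitudes reproducing Eapp at a given total signal.

    Inverts the spectral apparent-efficiency relation under the constraint
    k_DA·w_D + k_AD·w_A = total_counts; vectorized over arrays.
    """
    E = np.asarray(Eapp, dtype=float)
    T = np.asarray(total_counts, dtype=float)
    if np.any((E < 0) | (E > 1)):
        raise ValueError("Eapp field must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        rho = np.where(E > 0,
                       (1.0 / np.maximum(E, 1e-300) - 1.0)
                       * (pair.Q_D / pair.Q_A) * (pair.w_A / pair.w_D),
                       np.inf)
    donor_only = np.isinf(rho)
    rho_f = np.where(donor_only, 0.0, rho)
    k_ad = np.where(donor_only, 0.0, T / (rho_f * pair.w_D + pair.w_A))
    k_da = np.where(donor_only, T / pair.w_D, rho_f * k_ad)
    return k_da, k_ad


def render_spectral_image(Eapp_field: NDArray[np.float64],
                          intensity_field: NDArray[np.float64],
                          pair: FluorophorePair,
                          poisson_noise: bool = True,
                          seed: int | np.random.Generator = 0,
                          excitation: str = "800nm",
                          true_membrane_mask: NDArray[np.bool_] | None = None
                          ) -> SpectralImage:
    """Per-pixel mixed donor/acceptor spectra for a ground-truth Eapp field.

    Each pixel's spectrum is k_DA·f_D(λ) + k_AD·f_A(λ) on the donor
    emission grid, with amplitudes chosen so the spectral apparent
    efficiency equals that pixel's Eapp and the summed counts equal
    ``intensity_field``. Optional Poisson noise per wavelength plane.
    """
    E = np.asarray(Eapp_field, dtype=float)
    T = np.asarray(intensity_field, dtype=float)
    if E.shape != T.shape:
        raise ValueError("Eapp and intensity fields must share shape")
    if np.any(T < 0):
        raise ValueError("intensity must be non-negative")
    k_da, k_ad = spectral_amplitudes(E, T, pair)
    wl = pair.donor_emission.wavelengths
    f_d = pair.donor_emission.values
    f_a = pair.acceptor_emission.interpolate(wl)
    stack = (k_da[None, ...] * f_d.reshape(-1, *([1] * E.ndim))
             + k_ad[None, ...] * f_a.reshape(-1, *([1] * E.ndim)))
    if poisson_noise:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        stack = rng.poisson(np.maximum(stack, 0.0)).astype(float)
    return SpectralImage(stack=stack, wavelengths=wl, excitation=excitation,
                         ground_truth_eapp=E,
                         true_membrane_mask=true_membrane_mask)


def truncated_normal_field(mean: float, sd: float, shape: tuple[int, ...],
                           seed: int | np.random.Generator = 0,
                           lo: float = 0.0, hi: float = 1.0
                           ) -> NDArray[np.float64]:
    """Per-pixel ground-truth Eapp values ~ Normal(mean, sd) truncated
    to [lo, hi] (the physical support of a sensitized-emission estimate)."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = np.empty(int(np.prod(shape)))
    n = 0
    while n < out.size:
        draw = rng.normal(mean, sd, size=out.size - n)
        draw = draw[(draw >= lo) & (draw <= hi)]
        out[n:n + draw.size] = draw
        n += draw.size
    return out.reshape(shape)


def make_cell_outline_image(pair: FluorophorePair,
                            shape: tuple[int, int] = (120, 120),
                            radius_px: float = 40.0, width_px: float = 2.0,
                            eapp_mean: float = 0.3, eapp_sd: float = 0.05,
                            membrane_counts: float = 20000.0,
                            interior_counts: float = 1500.0,
                            background_counts: float = 30.0,
                            seed: int = 0,
                            poisson_noise: bool = True) -> SpectralImage:
    """Synthetic live-cell scene: a bright membrane outline on a dim body.

    The membrane is an annulus of the given radius/width carrying the FRET
    signal; the cell interior is dim donor-like signal; the exterior is
    near-dark. Returns the stack together with the true membrane mask.
    """
    rng = np.random.default_rng(seed)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(xx - (nx - 1) / 2.0, yy - (ny - 1) / 2.0)
    membrane = np.abs(r - radius_px) <= width_px / 2.0
    interior = r < radius_px - width_px / 2.0
    E = np.zeros(shape)
    E[membrane] = truncated_normal_field(eapp_mean, eapp_sd,
                                         (int(membrane.sum()),), seed=rng)
    T = np.full(shape, background_counts)
    T[interior] = interior_counts
    T[membrane] = membrane_counts
    return render_spectral_image(E, T, pair, poisson_noise=poisson_noise,
                                 seed=rng, true_membrane_mask=membrane)


# ---------------------------------------------------------------------------
# Michaelis–Menten datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticsDataset:
    """Initial-velocity data: substrate (µM) × replicate velocities (nM/min)."""

    substrate: NDArray[np.float64]  # µM, length n_S
    velocities: NDArray[np.float64]  # (n_replicates, n_S) nM product/min
    enzyme_conc: float  # nM
    cosubstrate: float | None = None  # µM, the fixed partner substrate
    time_min: float | None = None

    def __post_init__(self) -> None:
        sub = np.asarray(self.substrate, dtype=float)
        vel = np.atleast_2d(np.asarray(self.velocities, dtype=float))
        if np.any(sub <= 0):
            raise ValueError("substrate concentrations must be positive")
        if vel.shape[1] != sub.size:
            raise ValueError("velocity columns must match substrate grid")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme concentration must be positive")
        object.__setattr__(self, "substrate", sub)
        object.__setattr__(self, "velocities", vel)

    @property
    def n_replicates(self) -> int:
        return self.velocities.shape[0]

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, rep + 1, v)
                for rep in range(self.n_replicates)
                for s, v in zip(self.substrate, self.velocities[rep])]
        return pd.DataFrame(rows, columns=["substrate_uM", "replicate",
                                           "velocity_nM_per_min"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, enzyme_conc: float,
                   cosubstrate: float | None = None) -> "KineticsDataset":
        required = {"substrate_uM", "replicate", "velocity_nM_per_min"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"kinetics table missing columns: "
                             f"{sorted(missing)}")
        piv = frame.pivot_table(index="replicate", columns="substrate_uM",
                                values="velocity_nM_per_min")
        sub = piv.columns.to_numpy(dtype=float)
        order = np.argsort(sub)[::-1]
        return cls(substrate=sub[order],
                   velocities=piv.to_numpy(dtype=float)[:, order],
                   enzyme_conc=enzyme_conc, cosubstrate=cosubstrate)


def michaelis_menten_velocity(S, Km: float, kcat: float, E0: float):
    """v(S) = kcat·E0·S/(Km+S) — nM/min for kcat in min⁻¹ and E0 in nM."""
    S = np.asarray(S, dtype=float)
    return kcat * E0 * S / (Km + S)


def generate_mm_dataset(Km: float, kcat: float, E0: float,
                        substrate_grid: Sequence[float],
                        noise_cv: float = 0.0, n_replicates: int = 2,
                        seed: int | np.random.Generator = 0,
                        cosubstrate: float | None = None) -> KineticsDataset:
    """Michaelis–Menten initial velocities with multiplicative noise.

    Replicate velocities are the deterministic curve multiplied by
    lognormal noise of unit mean and coefficient of variation ``noise_cv``;
    ``noise_cv = 0`` gives the exact curve.
    """
    if min(Km, kcat, E0) <= 0:
        raise ValueError("Km, kcat and E0 must be positive")
    grid = np.asarray(list(substrate_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("substrate grid must be non-empty")
    v = michaelis_menten_velocity(grid, Km, kcat, E0)
    vel = np.tile(v, (n_replicates, 1))
    if noise_cv > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        s2 = np.log1p(noise_cv ** 2)
        noise = rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2),
                              size=vel.shape)
        vel = vel * noise
    return KineticsDataset(substrate=grid, velocities=vel, enzyme_conc=E0,
                           cosubstrate=cosubstrate)
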