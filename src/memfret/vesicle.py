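"""Confocal vesicle pipeline (quantitative imaging FRET).

Detects vesicles present in all three scans, fits the radial membrane
intensity profile (Gaussian on an error-function baseline), corrects
bleed-through and direct excitation, calibrates intensities to absolute
surface densities, and assembles per-vesicle apparent FRET efficiencies and
donor/acceptor concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import ndimage, optimize
from scipy.special import erf
from skimage import measure

from .photophysics import (BleedthroughCoefficients, FluorophorePair,
                           donor_quenching_efficiency,
                           reconstruct_unquenched_donor)
from .synthetic import OpticsParams, VesicleImageSet


@dataclass(frozen=True)
class VesicleBoundary:
    """Circle fit to the bright membrane ring of one vesicle."""

    center: tuple[float, float]  # pixel coords (x, y)
    radius: float  # µm
    circularity: float  # 1 − radial scatter / radius
    present_in_all_scans: bool

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class MembraneProfileFit:
    """Least-squares fit of a radial membrane cross-section.

    Model: I(d) = A·exp(−(d−d0)²/(2σ²))
                + (B/2)·(1 + erf((d−d0)/(√2·σ_b))) + C,
    with d the signed distance along the outward normal. The integrated
    membrane signal per unit length of circumference is A·σ·√(2π).
    """

    amplitude: float  # A, counts/pixel
    center: float  # d0, µm
    sigma: float  # µm
    step_height: float  # B, counts/pixel (signed: interior→exterior)
    offset: float  # C, counts/pixel
    baseline_sigma: float  # σ_b, µm
    rss: float
    r_squared: float
    converged: bool

    @property
    def membrane_integral(self) -> float:
        """A·σ·√(2π): profile area above baseline (counts·µm/pixel)."""
        return self.amplitude * self.sigma * np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class ConcentrationCalibration:
    """Counts-per-molecule slopes from standard-solution imaging.

    ``slope_donor`` converts unquenched donor intensity per µm² to
    donors/µm²; ``slope_acceptor`` converts acceptor-scan intensity per µm²
    to acceptors/µm². Units: counts·µm²/molecule.
    """

    slope_donor: float
    slope_acceptor: float
    source: str = "standard solutions"

    def __post_init__(self) -> None:
        if self.slope_donor <= 0 or self.slope_acceptor <= 0:
            raise ValueError("calibration slopes must be positive")

    @classmethod
    def from_optics(cls, optics: OpticsParams,
                    pair: FluorophorePair) -> "ConcentrationCalibration":
        """The calibration a standard-solution measurement would deliver
        for a render with these optics (counts per molecule = gain·Q)."""
        return cls(slope_donor=optics.gain_donor * pair.Q_D,
                   slope_acceptor=optics.gain_acceptor * pair.Q_A,
                   source="render optics")


@dataclass(frozen=True)
class VesicleMeasurement:
    """One vesicle's quantitation."""

    boundary: VesicleBoundary
    I_Dm: float  # donor membrane intensity per µm² (with RET)
    F_sens: float  # sensitized acceptor intensity per µm²
    I_Am: float  # acceptor-scan intensity per µm²
    I_Dcorr: float  # reconstructed unquenched donor intensity per µm²
    Eapp: float
    sigma_D: float  # molecules/µm²
    sigma_A: float
    x_a: float
    qc_flags: tuple[str, ...] = ()

    @property
    def total_density(self) -> float:
        return self.sigma_D + self.sigma_A


MEASUREMENT_COLUMNS = ["center_x", "center_y", "radius_um", "circularity",
                       "I_Dm", "F_sens", "I_Am", "I_Dcorr", "Eapp",
                       "sigma_D", "sigma_A", "x_a", "qc_flags"]


def measurements_to_frame(measurements: list[VesicleMeasurement]
                          ) -> pd.DataFrame:
    rows = []
    for m in measurements:
        rows.append({
            "center_x": m.boundary.center[0],
            "center_y": m.boundary.center[1],
            "radius_um": m.boundary.radius,
            "circularity": m.boundary.circularity,
            "I_Dm": m.I_Dm, "F_sens": m.F_sens, "I_Am": m.I_Am,
            "I_Dcorr": m.I_Dcorr, "Eapp": m.Eapp,
            "sigma_D": m.sigma_D, "sigma_A": m.sigma_A, "x_a": m.x_a,
            "qc_flags": ";".join(m.qc_flags),
        })
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def frame_to_measurements(frame: pd.DataFrame) -> list[VesicleMeasurement]:
    missing = set(MEASUREMENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"vesicle table missing columns: {sorted(missing)}")
    out = []
    for _, r in frame.iterrows():
        flags = tuple(str(r["qc_flags"]).split(";")) if (
            isinstance(r["qc_flags"], str) and r["qc_flags"]) else ()
        out.append(VesicleMeasurement(
            boundary=VesicleBoundary(
                center=(float(r["center_x"]), float(r["center_y"])),
                radius=float(r["radius_um"]),
                circularity=float(r["circularity"]),
                present_in_all_scans=True),
            I_Dm=float(r["I_Dm"]), F_sens=float(r["F_sens"]),
            I_Am=float(r["I_Am"]), I_Dcorr=float(r["I_Dcorr"]),
            Eapp=float(r["Eapp"]), sigma_D=float(r["sigma_D"]),
            sigma_A=float(r["sigma_A"]), x_a=float(r["x_a"]),
            qc_flags=flags))
    return out


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DetectionConfig:
    smooth_sigma_px: float = 1.5
    threshold_sds: float = 4.0  # above robust background
    min_ring_pixels: int = 60
    min_circularity: float = 0.9
    min_angular_coverage: float = 0.9  # fraction of angular bins occupied
    min_ring_contrast: float = 0.3  # peak above lumen, fraction of peak
    presence_snr: float = 5.0  # ring-peak s.e. multiples per scan


def _robust_background(img: NDArray[np.float64]) -> tuple[float, float]:
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    return med, 1.4826 * mad + 1e-9


def detect_vesicles(images: VesicleImageSet,
                    config: DetectionConfig = DetectionConfig()
                    ) -> tuple[list[VesicleBoundary], list[str]]:
    """Find vesicle boundaries on the summed image and QC them.

    Bright ring pixels are segmented on the Gaussian-smoothed sum of the
    three scans; each connected ring gives a circle (intensity-weighted
    centroid, mean radial distance). A vesicle is kept when the ring is
    circular, angularly complete, and shows membrane contrast in *all
    three* scans. Returns (boundaries, rejection log). A flat or empty
    image yields an empty list.
    """
    optics = images.optics
    total = images.donor_scan + images.acceptor_scan + images.fret_scan
    smooth = ndimage.gaussian_filter(total, config.smooth_sigma_px)
    med, sd = _robust_background(smooth)
    mask = smooth > med + config.threshold_sds * sd
    labels = measure.label(mask)
    boundaries: list[VesicleBoundary] = []
    log: list[str] = []
    for region in measure.regionprops(labels, intensity_image=smooth):
        if region.num_pixels < config.min_ring_pixels:
            log.append(f"region at {region.centroid}: too few ring pixels")
            continue
        coords = region.coords  # (row, col)
        weights = np.maximum(smooth[coords[:, 0], coords[:, 1]] - med, 0.0)
        cy = float(np.average(coords[:, 0], weights=weights))
        cx = float(np.average(coords[:, 1], weights=weights))
        r_px = np.hypot(coords[:, 1] - cx, coords[:, 0] - cy)
        # the membrane ring is the radial intensity peak around the centroid
        # (the region may be a filled disk when the lumen is brighter than
        # the bath)
        r_int = np.round(r_px).astype(int)
        prof = np.bincount(r_int, weights=weights)
        norm_n = np.maximum(np.bincount(r_int), 1)
        prof = prof / norm_n
        peak_r = int(np.argmax(prof))
        if peak_r <= 2:
            log.append(f"region at ({cx:.0f},{cy:.0f}): not a ring")
            continue
        window = max(3.0, 2.0 * config.smooth_sigma_px)
        on_ring = np.abs(r_px - peak_r) <= window
        ring_w = weights[on_ring]
        if ring_w.sum() <= 0:
            log.append(f"region at ({cx:.0f},{cy:.0f}): empty ring")
            continue
        # a membrane is a radial *peak*: a filled disk (bright lumen on a
        # dim bath) has no contrast between the ring and its interior
        inner = prof[1:max(peak_r - int(window), 2)]
        interior_level = float(inner.mean()) if inner.size else 0.0
        peak_val = float(prof[peak_r])
        if peak_val - interior_level < config.min_ring_contrast * peak_val:
            log.append(f"region at ({cx:.0f},{cy:.0f}): no membrane peak "
                       "above the lumen level")
            continue
        radius_px = float(np.average(r_px[on_ring], weights=ring_w))
        # circularity: spread of per-angle ring radii around the mean
        ang = np.mod(np.arctan2(coords[on_ring, 0] - cy,
                                coords[on_ring, 1] - cx), 2 * np.pi)
        abin = (ang / (2 * np.pi) * 36).astype(int)
        sum_w = np.bincount(abin, weights=ring_w, minlength=36)
        sum_wr = np.bincount(abin, weights=ring_w * r_px[on_ring],
                             minlength=36)
        occupied = sum_w > 0
        coverage = float(occupied.sum()) / 36.0
        r_angle = sum_wr[occupied] / sum_w[occupied]
        circ = 1.0 - float(r_angle.std()) / radius_px
        if circ < config.min_circularity or coverage < \
                config.min_angular_coverage:
            log.append(f"vesicle at ({cx:.0f},{cy:.0f}): "
                       f"circularity {circ:.2f} / coverage {coverage:.2f} "
                       "below threshold")
            continue
        # per-channel presence: the membrane peak must rise above the
        # midpoint of the flanking annuli. For a channel carrying only the
        # interior/exterior background step, the erf midpoint at the ring
        # equals that flank average exactly, so the contrast is ~0; a dim
        # but real membrane still stands out against the s.e. of the mean.
        present = True
        w_pk = max(2.0, config.smooth_sigma_px)
        pk_band = np.abs(r_px - radius_px) <= w_pk
        in_band = (r_px < radius_px - 2 * w_pk) & (r_px > radius_px
                                                   - 5 * w_pk)
        out_band = (r_px > radius_px + 2 * w_pk) & (r_px < radius_px
                                                    + 5 * w_pk)
        for name, img in images.channels.items():
            vals = img[coords[:, 0], coords[:, 1]]
            peak = float(vals[pk_band].mean()) if pk_band.any() else 0.0
            flank = []
            for band in (in_band, out_band):
                if band.any():
                    flank.append(float(vals[band].mean()))
            baseline = float(np.mean(flank)) if flank else 0.0
            _, ch_sd = _robust_background(img)
            floor = max(ch_sd, optics.read_noise_sd, 1e-9)
            sem = floor / np.sqrt(max(pk_band.sum(), 1))
            if peak - baseline < config.presence_snr * sem:
                present = False
                log.append(f"vesicle at ({cx:.0f},{cy:.0f}): absent from "
                           f"{name} scan")
                break
        if not present:
            continue
        boundaries.append(VesicleBoundary(
            center=(cx, cy), radius=radius_px * optics.pixel_size,
            circularity=circ, present_in_all_scans=True))
    return boundaries, log


# ---------------------------------------------------------------------------
# Membrane profile fitting
# ---------------------------------------------------------------------------


def _profile_model(d, A, d0, sigma, B, C, sigma_b):
    return (A * np.exp(-0.5 * ((d - d0) / sigma) ** 2)
            + 0.5 * B * (1.0 + erf((d - d0) / (np.sqrt(2.0) * sigma_b)))
            + C)


def fit_membrane_profile(distance: NDArray[np.float64],
                         intensity: NDArray[np.float64],
                         psf_sigma_guess: float = 0.2,
                         tie_baseline_sigma: bool = False
                         ) -> MembraneProfileFit:
    """Fit I(d) = Gaussian membrane peak + error-function baseline step.

    ``distance`` is the signed distance across the membrane (µm, increasing
    outward, zero near the expected ring). The step sign is fitted, not
    assumed. With ``tie_baseline_sigma`` the step width is constrained to
    the Gaussian width (both arise from the same PSF), which conditions the
    fit much better when the membrane peak is weak relative to the
    baseline. Non-convergence is reported honestly via ``converged``.
    """
    d = np.asarray(distance, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if d.size != y.size or d.size < 8:
        raise ValueError("profile needs matching arrays of at least 8 points")
    inner = float(np.median(y[d < np.quantile(d, 0.15)]))
    outer = float(np.median(y[d > np.quantile(d, 0.85)]))
    a0 = max(float(y.max()) - max(inner, outer), 1e-3)
    span = float(d.max() - d.min())
    if tie_baseline_sigma:
        def model(dd, A, d0, sigma, B, C):
            return _profile_model(dd, A, d0, sigma, B, C, sigma)

        p0 = [a0, float(d[np.argmax(y)]), psf_sigma_guess, outer - inner,
              inner]
        lb = [0.0, d.min(), 0.02 * span, -np.inf, -np.inf]
        ub = [np.inf, d.max(), span, np.inf, np.inf]
    else:
        model = _profile_model
        p0 = [a0, float(d[np.argmax(y)]), psf_sigma_guess, outer - inner,
              inner, psf_sigma_guess]
        lb = [0.0, d.min(), 0.02 * span, -np.inf, -np.inf, 0.02 * span]
        ub = [np.inf, d.max(), span, np.inf, np.inf, span]
    try:
        popt, _ = optimize.curve_fit(model, d, y, p0=p0,
                                     bounds=(lb, ub), maxfev=20000)
        converged = True
    except (RuntimeError, ValueError):
        popt = p0
        converged = False
    if tie_baseline_sigma:
        popt = list(popt) + [popt[2]]
    resid = y - _profile_model(d, *popt)
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return MembraneProfileFit(amplitude=float(popt[0]), center=float(popt[1]),
                              sigma=float(popt[2]), step_height=float(popt[3]),
                              offset=float(popt[4]),
                              baseline_sigma=float(popt[5]), rss=rss,
                              r_squared=r2, converged=converged)


def radial_profile(image: NDArray[np.float64], boundary: VesicleBoundary,
                   pixel_size: float, half_width_um: float = 1.0,
                   n_angles: int = 360, n_samples: int = 81
                   ) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Angle-averaged radial intensity profile across the membrane ring.

    Samples the image along outward normals at evenly spaced angles
    (cubic-spline interpolation), aligned on the detected ring, and
    averages. Returns (signed distance µm, mean intensity counts/pixel).
    """
    cx, cy = boundary.center
    r0_px = boundary.radius / pixel_size
    offsets = np.linspace(-half_width_um, half_width_um, n_samples)
    ang = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    rr = r0_px + offsets[None, :] / pixel_size
    xs = cx + np.cos(ang)[:, None] * rr
    ys = cy + np.sin(ang)[:, None] * rr
    vals = ndimage.map_coordinates(image, [ys.ravel(), xs.ravel()], order=3,
                                   mode="nearest").reshape(n_angles,
                                                           n_samples)
    return offsets, vals.mean(axis=0)


# ---------------------------------------------------------------------------
# Corrections and calibration
# ---------------------------------------------------------------------------


def correct_bleedthrough(I_Dm: float, I_Am: float, fret_raw: float,
                         coeffs: BleedthroughCoefficients
                         ) -> tuple[float, list[str]]:
    """Sensitized emission after removing bleed-through contributions.

    F_sens = fret_raw − donor_into_fret·I_Dm − acceptor_direct·I_Am.
    A corrected value below zero is returned as-is with a QC flag (noise
    can produce small negatives; clipping would bias downstream fits).
    """
    f = (fret_raw - coeffs.donor_into_fret * I_Dm
         - coeffs.acceptor_direct_excitation * I_Am)
    flags = ["negative_sensitized_emission"] if f < 0 else []
    return f, flags


def estimate_bleedthrough(donor_standard: VesicleImageSet | None = None,
                          acceptor_standard: VesicleImageSet | None = None,
                          threshold_quantile: float = 0.9
                          ) -> BleedthroughCoefficients:
    """Bleed-through coefficients from single-fluorophore standards.

    For a donor-only standard: donor_into_fret = mean FRET-scan / donor-scan
    ratio over bright donor pixels. For an acceptor-only standard:
    acceptor_direct_excitation = FRET-scan / acceptor-scan ratio over bright
    acceptor pixels. Intensities are background-subtracted (robust median),
    making the coefficients invariant to overall intensity scaling.
    """
    def ratio(images: VesicleImageSet, on: str) -> float:
        on_img = images.channels[on]
        off_img = images.fret_scan
        on_med, on_sd = _robust_background(on_img)
        off_med, _ = _robust_background(off_img)
        on_sub = on_img - on_med
        bright = on_sub > np.quantile(on_sub, threshold_quantile)
        on_sig = on_sub[bright]
        if float(on_sig.mean()) <= 3.0 * on_sd:
            raise ValueError(f"{on} standard has no usable on-channel signal")
        return float(np.clip((off_img - off_med)[bright].sum()
                             / on_sig.sum(), 0.0, None))

    donor_into_fret = ratio(donor_standard, "donor") if donor_standard else 0.0
    acc_direct = (ratio(acceptor_standard, "acceptor")
                  if acceptor_standard else 0.0)
    return BleedthroughCoefficients(donor_into_fret=donor_into_fret,
                                    acceptor_direct_excitation=acc_direct)


def calibrate_concentration(intensity_per_um2: float, slope: float) -> float:
    """molecules/µm² = intensity per µm² / calibration slope."""
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    return intensity_per_um2 / slope


# ---------------------------------------------------------------------------
# Per-vesicle measurement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeasurementConfig:
    min_profile_r2: float = 0.95
    min_amplitude_read_noise: float = 3.0
    half_width_um: float = 1.0
    n_angles: int = 360


class VesicleExcluded(Exception):
    """A vesicle failed quantitation QC; ``reason`` says why."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def measure_vesicle(images: VesicleImageSet, boundary: VesicleBoundary,
                    pair: FluorophorePair,
                    coeffs: BleedthroughCoefficients,
                    calib: ConcentrationCalibration,
                    config: MeasurementConfig = MeasurementConfig()
                    ) -> VesicleMeasurement:
    """Quantify one vesicle: intensities, Eapp, absolute densities.

    Fits the angle-averaged membrane profile in each scan; converts the
    Gaussian integral to intensity per µm² of membrane using the optical
    section height; removes bleed-through; reconstructs the unquenched
    donor signal; and calibrates densities. Raises
    :class:`VesicleExcluded` on any QC failure.
    """
    optics = images.optics
    flags: list[str] = []

    def sample_profiles(bnd: VesicleBoundary):
        profs = {}
        dd = None
        for name, img in images.channels.items():
            dd, prof = radial_profile(img, bnd, optics.pixel_size,
                                      half_width_um=config.half_width_um,
                                      n_angles=config.n_angles)
            profs[name] = prof
        return dd, profs

    # first pass: locate the ring precisely from the summed profile, then
    # re-sample with the window centered on it
    dist, profiles = sample_profiles(boundary)
    first = fit_membrane_profile(
        dist, profiles["donor"] + profiles["acceptor"] + profiles["fret"],
        psf_sigma_guess=optics.membrane_psf_sigma, tie_baseline_sigma=True)
    if first.converged and abs(first.center) > 0.02:
        boundary = VesicleBoundary(
            center=boundary.center,
            radius=max(boundary.radius + first.center, optics.pixel_size),
            circularity=boundary.circularity,
            present_in_all_scans=boundary.present_in_all_scans)
        dist, profiles = sample_profiles(boundary)

    # the three scans see the same vesicle through the same PSF, so the
    # profile geometry (d0, σ, σ_b) is shared: fit it once on the summed
    # profile, then solve each channel's amplitudes linearly (an
    # unconstrained linear solve cannot trade amplitude against baseline
    # width the way independent nonlinear fits can at low SNR)
    total = profiles["donor"] + profiles["acceptor"] + profiles["fret"]
    shape_fit = fit_membrane_profile(
        dist, total, psf_sigma_guess=optics.membrane_psf_sigma,
        tie_baseline_sigma=True)
    if not shape_fit.converged:
        raise VesicleExcluded("summed profile fit did not converge")
    if shape_fit.r_squared < config.min_profile_r2:
        raise VesicleExcluded(
            f"summed profile fit R²={shape_fit.r_squared:.3f} below "
            f"{config.min_profile_r2}")
    gauss = np.exp(-0.5 * ((dist - shape_fit.center) / shape_fit.sigma) ** 2)
    step = 0.5 * (1.0 + erf((dist - shape_fit.center)
                            / (np.sqrt(2.0) * shape_fit.baseline_sigma)))
    design = np.column_stack([gauss, step, np.ones_like(dist)])
    per_um2: dict[str, float] = {}
    for name, prof in profiles.items():
        coef, *_ = np.linalg.lstsq(design, prof, rcond=None)
        amplitude = float(coef[0])
        resid = prof - design @ coef
        tss = float(((prof - prof.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
        if name == "donor":
            if amplitude < config.min_amplitude_read_noise * \
                    optics.read_noise_sd:
                raise VesicleExcluded(
                    "donor membrane amplitude at noise floor")
            if r2 < config.min_profile_r2:
                raise VesicleExcluded(
                    f"donor profile R²={r2:.3f} below "
                    f"{config.min_profile_r2}")
        # counts/µm of circumference, then per µm² of membrane
        integral = amplitude * shape_fit.sigma * np.sqrt(2.0 * np.pi)
        lam = integral / optics.pixel_size ** 2
        per_um2[name] = lam / optics.section_height

    F_sens, bt_flags = correct_bleedthrough(per_um2["donor"],
                                            per_um2["acceptor"],
                                            per_um2["fret"], coeffs)
    flags.extend(bt_flags)
    I_Dm = per_um2["donor"]
    I_Dcorr = reconstruct_unquenched_donor(I_Dm, max(F_sens, 0.0), pair,
                                           gain_ratio=optics.gain_ratio)
    if I_Dcorr <= 0:
        raise VesicleExcluded("no donor signal after reconstruction")
    Eapp = donor_quenching_efficiency(I_Dm, I_Dcorr)
    if Eapp < 0:
        flags.append("negative_efficiency")
    sigma_D = calibrate_concentration(I_Dcorr, calib.slope_donor)
    sigma_A = calibrate_concentration(max(per_um2["acceptor"], 0.0),
                                      calib.slope_acceptor)
    denom = sigma_A + sigma_D
    if denom <= 0:
        raise VesicleExcluded("no labeled receptors detected")
    return VesicleMeasurement(boundary=boundary, I_Dm=I_Dm, F_sens=F_sens,
                              I_Am=per_um2["acceptor"], I_Dcorr=I_Dcorr,
                              Eapp=Eapp, sigma_D=sigma_D, sigma_A=sigma_A,
                              x_a=sigma_A / denom, qc_flags=tuple(flags))


def measure_image_set(images: VesicleImageSet, pair: FluorophorePair,
                      coeffs: BleedthroughCoefficients | None = None,
                      calib: ConcentrationCalibration | None = None,
                      detection: DetectionConfig = DetectionConfig(),
                      config: MeasurementConfig = MeasurementConfig()
                      ) -> tuple[list[VesicleMeasurement], list[str]]:
    """Detect and measure every vesicle in one image set.

    Bleed-through defaults to the pair's stored coefficients; calibration
    defaults to the render-optics slopes (the synthetic analogue of the
    standard-solution calibration).
    """
    coeffs = coeffs if coeffs is not None else images.pair.bleedthrough
    calib = calib if calib is not None else ConcentrationCalibration. \
        from_optics(images.optics, pair)
    boundaries, log = detect_vesicles(images, detection)
    out = []
    for b in boundaries:
        try:
            out.append(measure_vesicle(images, b, pair, coeffs, calib,
                                       config))
        except VesicleExcluded as exc:
            log.append(f"vesicle at ({b.center[0]:.0f},{b.center[1]:.0f}) "
                       f"excluded: {exc.reason}")
    return out, log
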