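"""Intrinsic FRET, density binning, and monomer–dimer model fitting.

Converts per-vesicle measurements into intrinsic FRET
(Eapp − E_proximity)/x_a, bins vesicles along total receptor density, and
fits either the two-state (monomer–dimer mass-action) association model —
value(T) = Ẽ·dimer_fraction(T; Kd) rising to the plateau Ẽ — or a
horizontal line (inverse-variance-weighted mean) for constitutive behavior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .photophysics import DEFAULT_R_EXCLUSION, proximity_fret_mc
from .synthetic import dimer_fraction
from .vesicle import VesicleMeasurement


@dataclass(frozen=True)
class BinnedFretPoint:
    """One equal-count bin of vesicles (means ± spread in x and y)."""

    mean_total_density: float  # donors+acceptors, molecules/µm²
    density_spread: float
    mean_value: float  # Eapp or intrinsic FRET
    value_spread: float
    n_vesicles: int
    mean_sigma_A: float = 0.0  # acceptor density, drives proximity FRET
    mean_x_a: float = 0.0

    def __post_init__(self) -> None:
        if self.n_vesicles < 1:
            raise ValueError("bins must contain vesicles")
        if self.density_spread < 0 or self.value_spread < 0:
            raise ValueError("spreads must be non-negative")


@dataclass(frozen=True)
class DimerFitResult:
    """Fitted association or horizontal model."""

    model: Literal["association", "horizontal"]
    plateau: float  # Ẽ for association; the y intercept for horizontal
    plateau_stderr: float
    Kd2d: float | None = None
    Kd2d_stderr: float | None = None
    rss: float = np.nan
    n_points: int = 0
    aic: float = np.nan
    converged: bool = True
    flags: tuple[str, ...] = ()


def intrinsic_fret(Eapp: float, E_proximity: float, x_a: float) -> float:
    """Intrinsic FRET = (Eapp − E_proximity)/x_a.

    Divides out the probability x_a that a donor's dimer partner carries an
    acceptor and removes the random-proximity contribution. Values may be
    slightly negative under noise; they are kept so downstream fits stay
    unbiased.
    """
    if not 0.0 < x_a <= 1.0:
        raise ValueError("x_a must lie in (0, 1] (vesicle excluded at 0)")
    if not 0.0 <= E_proximity < 1.0:
        raise ValueError("E_proximity must lie in [0, 1)")
    return (Eapp - E_proximity) / x_a


def bin_measurements(measurements: Sequence[VesicleMeasurement],
                     min_per_bin: int = 8,
                     spread: Literal["sd", "sem"] = "sem",
                     value: Literal["Eapp"] = "Eapp"
                     ) -> list[list[VesicleMeasurement]]:
    """Equal-count bins of vesicles ordered by total receptor density.

    Every measurement lands in exactly one bin; each bin holds at least
    ``min_per_bin`` vesicles (the remainder joins the last bin). Input
    order is irrelevant. Fewer than ``min_per_bin`` measurements give an
    empty result.
    """
    ms = sorted(measurements, key=lambda m: (m.total_density, m.Eapp))
    n = len(ms)
    if n < min_per_bin:
        return []
    n_bins = n // min_per_bin
    edges = np.linspace(0, n, n_bins + 1).astype(int)
    return [ms[a:b] for a, b in zip(edges[:-1], edges[1:])]


def _spread(vals: np.ndarray, kind: str) -> float:
    if len(vals) < 2:
        return 0.0
    sd = float(vals.std(ddof=1))
    return sd if kind == "sd" else sd / np.sqrt(len(vals))


def summarize_bins(bins: Sequence[Sequence[VesicleMeasurement]],
                   values_per_bin: Sequence[np.ndarray] | None = None,
                   spread: Literal["sd", "sem"] = "sem"
                   ) -> list[BinnedFretPoint]:
    """Per-bin means and spreads (x = total density, y = Eapp or supplied)."""
    points = []
    for i, bin_ms in enumerate(bins):
        dens = np.array([m.total_density for m in bin_ms])
        vals = (np.asarray(values_per_bin[i]) if values_per_bin is not None
                else np.array([m.Eapp for m in bin_ms]))
        points.append(BinnedFretPoint(
            mean_total_density=float(dens.mean()),
            density_spread=_spread(dens, spread),
            mean_value=float(vals.mean()),
            value_spread=_spread(vals, spread),
            n_vesicles=len(bin_ms),
            mean_sigma_A=float(np.mean([m.sigma_A for m in bin_ms])),
            mean_x_a=float(np.mean([m.x_a for m in bin_ms]))))
    return points


def intrinsic_fret_bins(measurements: Sequence[VesicleMeasurement],
                        R0: float,
                        r_exclusion: float = DEFAULT_R_EXCLUSION,
                        min_per_bin: int = 8,
                        spread: Literal["sd", "sem"] = "sem",
                        proximity: Literal["mc", "constant", "none"] = "mc",
                        proximity_constant: float = 0.0,
                        n_realizations: int = 100,
                        seed: int = 0,
                        composition: tuple[float, float | None] | None = None
                        ) -> list[BinnedFretPoint]:
    """Bin vesicles and convert each bin to intrinsic FRET points.

    The proximity correction is evaluated per bin at that bin's mean
    acceptor density (Monte Carlo by default; a global constant or none for
    sensitivity analysis), then applied per vesicle together with that
    vesicle's own measured x_a. Vesicles with x_a = 0 are excluded.

    ``composition`` = (E_dimer, Kd2d or None) enables the self-consistent
    mixture correction: transfer-rate competition means a dimerized donor
    gains less from random neighbours than a monomer, so once a first-pass
    fit supplies the dimer efficiency (and Kd, or None for a fully
    constitutive dimer), the per-bin proximity term is re-evaluated for the
    mixed population.
    """
    usable = [m for m in measurements if m.x_a > 0]
    bins = bin_measurements(usable, min_per_bin=min_per_bin)
    values = []
    rng = np.random.default_rng(seed)
    for bin_ms in bins:
        if proximity == "mc":
            sig_a = float(np.mean([m.sigma_A for m in bin_ms]))
            sig_d = float(np.mean([m.sigma_D for m in bin_ms]))
            p_partner, e_partner = 0.0, 0.0
            if composition is not None:
                e_partner = float(np.clip(composition[0], 0.0, 0.99))
                kd = composition[1]
                mean_t = float(np.mean([m.total_density for m in bin_ms]))
                frac = 1.0 if kd is None else float(dimer_fraction(mean_t,
                                                                   kd))
                x_bar = float(np.mean([m.x_a for m in bin_ms]))
                p_partner = float(np.clip(frac * x_bar, 0.0, 1.0))
            e_prox = proximity_fret_mc(sig_d, sig_a, R0,
                                       r_exclusion=r_exclusion,
                                       n_realizations=n_realizations,
                                       seed=rng, p_partner=p_partner,
                                       E_partner=e_partner).E_proximity
        elif proximity == "constant":
            e_prox = proximity_constant
        else:
            e_prox = 0.0
        values.append(np.array([intrinsic_fret(m.Eapp, e_prox, m.x_a)
                                for m in bin_ms]))
    return summarize_bins(bins, values_per_bin=values, spread=spread)


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------


def _weights(points: Sequence[BinnedFretPoint]) -> np.ndarray:
    spreads = np.array([p.value_spread for p in points])
    positive = spreads[spreads > 0]
    if positive.size == 0:
        return np.ones(len(points))
    fallback = float(np.median(positive))
    spreads = np.where(spreads > 0, spreads, fallback)
    return 1.0 / spreads ** 2


def fit_horizontal(points: Sequence[BinnedFretPoint]) -> DimerFitResult:
    """Inverse-variance-weighted mean of the bin values (flat model).

    Bins with zero spread receive the median positive weight so a single
    noiseless bin cannot dominate.
    """
    if len(points) < 1:
        raise ValueError("need at least one bin")
    y = np.array([p.mean_value for p in points])
    w = _weights(points)
    intercept = float(np.sum(w * y) / np.sum(w))
    stderr = float(1.0 / np.sqrt(np.sum(w)))
    rss = float(np.sum(w * (y - intercept) ** 2))
    n = len(points)
    aic = n * np.log(max(rss, 1e-300) / n) + 2.0
    return DimerFitResult(model="horizontal", plateau=intercept,
                          plateau_stderr=stderr, rss=rss, n_points=n,
                          aic=aic)


def fit_association_model(points: Sequence[BinnedFretPoint],
                          kd_bounds: tuple[float, float] = (1e-3, 1e7)
                          ) -> DimerFitResult:
    """Weighted fit of value(T) = Ẽ·dimer_fraction(T; Kd2d).

    The plateau Ẽ is the pairwise FRET efficiency of the dimer (the curve's
    "peak value"); Kd2d is the 2-D dissociation constant in molecules/µm².
    Multi-start over a log-spaced Kd grid; standard errors from the
    Jacobian covariance. Requires ≥ 3 bins spanning a ≥ 4-fold density
    range. Flat-at-zero data yield Ẽ ≈ 0 with an unidentifiable-Kd flag.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 bins")
    T = np.array([p.mean_total_density for p in points])
    if T.max() < 4.0 * T.min():
        raise ValueError("bins must span at least a 4-fold density range")
    y = np.array([p.mean_value for p in points])
    w = _weights(points)
    sigma = 1.0 / np.sqrt(w)

    def model(t, etilde, kd):
        return etilde * dimer_fraction(t, kd)

    best = None
    for kd0 in np.geomspace(max(T.min() * 0.05, kd_bounds[0]),
                            min(T.max() * 20.0, kd_bounds[1]), 7):
        f0 = dimer_fraction(T, kd0)
        e0 = float(np.clip(np.sum(w * y * f0) / np.sum(w * f0 ** 2),
                           1e-6, 1.5)) if np.any(f0 > 0) else 0.1
        try:
            popt, pcov = optimize.curve_fit(
                model, T, y, p0=[e0, kd0], sigma=sigma, absolute_sigma=True,
                bounds=([-0.5, kd_bounds[0]], [1.5, kd_bounds[1]]),
                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = (y - model(T, *popt)) / sigma
        rss = float(resid @ resid)
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    flags: list[str] = []
    if best is None:
        return DimerFitResult(model="association", plateau=np.nan,
                              plateau_stderr=np.nan, Kd2d=np.nan,
                              Kd2d_stderr=np.nan, n_points=len(points),
                              converged=False, flags=("no_convergence",))
    popt, pcov, rss = best
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    etilde, kd = float(popt[0]), float(popt[1])
    if abs(etilde) < 3.0 * perr[0] and abs(etilde) < 0.02:
        flags.append("plateau_consistent_with_zero")
        flags.append("kd_unidentifiable")
    if kd <= T.min() * 1e-2 or not np.isfinite(perr[1]) or \
            perr[1] > 10.0 * kd:
        # saturated everywhere: the plateau is just the weighted mean
        flags.append("kd_unidentifiable")
    n = len(points)
    aic = n * np.log(max(rss, 1e-300) / n) + 4.0
    return DimerFitResult(model="association", plateau=etilde,
                          plateau_stderr=float(perr[0]), Kd2d=kd,
                          Kd2d_stderr=float(perr[1]), rss=rss, n_points=n,
                          aic=aic, converged=True, flags=tuple(flags))


def compare_models(points: Sequence[BinnedFretPoint],
                   aic_margin: float = 2.0) -> dict:
    """Fit both models and recommend one by AIC (Δ ≥ 2), else indeterminate.

    Requires ≥ 4 bins so the association model's extra parameter can be
    penalized meaningfully.
    """
    if len(points) < 4:
        raise ValueError("model comparison needs at least 4 bins")
    assoc = fit_association_model(points)
    horiz = fit_horizontal(points)
    delta = horiz.aic - assoc.aic
    if not assoc.converged:
        rec = "horizontal"
    elif delta >= aic_margin:
        rec = "association"
    elif delta <= -aic_margin:
        rec = "horizontal"
    else:
        rec = "indeterminate"
    return {"recommended": rec, "association": assoc, "horizontal": horiz,
            "delta_aic": float(delta)}
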