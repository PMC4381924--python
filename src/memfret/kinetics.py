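"""Steady-state Michaelis–Menten kinetics with duplicate handling.

Nonlinear least-squares fits of v = Vmax·S/(Km+S) to initial-velocity data,
turnover numbers per active site, specificity constants, censored
lower-bound reporting when curvature is absent, and linear-range /
substrate-turnover diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy import optimize, stats

from .synthetic import KineticsDataset, michaelis_menten_velocity


@dataclass(frozen=True)
class MMFitResult:
    """Fitted apparent Michaelis–Menten parameters.

    ``kcat`` is per supplied enzyme active-site concentration (min⁻¹);
    standard deviations come from fitting duplicates separately. When the
    data show no curvature, ``Km_app``/``kcat`` are lower bounds and
    ``censored`` is set.
    """

    Km_app: float  # µM
    kcat: float  # min⁻¹
    Vmax: float  # nM/min
    Km_sd: float
    kcat_sd: float
    converged: bool
    censored: bool = False
    flags: tuple[str, ...] = ()

    @property
    def specificity(self) -> float:
        """kcat/Km_app in µM⁻¹·min⁻¹ (unrounded)."""
        return self.kcat / self.Km_app


def _fit_once(S: NDArray[np.float64], v: NDArray[np.float64]
              ) -> tuple[float, float, bool]:
    """Single MM fit; returns (Km, Vmax, converged)."""
    vmax0 = float(v.max())
    km0 = float(np.median(S))
    try:
        popt, _ = optimize.curve_fit(
            lambda s, vmax, km: vmax * s / (km + s), S, v,
            p0=[vmax0, km0], bounds=([0.0, 1e-9], [np.inf, np.inf]),
            maxfev=20000)
        return float(popt[1]), float(popt[0]), True
    except (RuntimeError, ValueError):
        return km0, vmax0, False


def fit_michaelis_menten(data: KineticsDataset) -> MMFitResult:
    """Fit v = Vmax·S/(Km+S); kcat = Vmax/E0.

    Duplicates are fit jointly for the headline parameters; the reported
    standard deviations come from fitting each replicate separately and
    taking the s.d. of the per-replicate parameters. Data with no
    detectable curvature (v ∝ S throughout, Km beyond the substrate range)
    are reported as censored lower bounds: Km_app > max(S).
    """
    if data.substrate.size < 4:
        raise ValueError("need at least 4 substrate levels")
    S_all = np.tile(data.substrate, data.n_replicates)
    v_all = data.velocities.ravel()
    km, vmax, ok = _fit_once(S_all, v_all)

    per_rep = []
    if data.n_replicates >= 2:
        for rep in range(data.n_replicates):
            km_r, vmax_r, ok_r = _fit_once(data.substrate,
                                           data.velocities[rep])
            if ok_r:
                per_rep.append((km_r, vmax_r))
    if len(per_rep) >= 2:
        kms = np.array([p[0] for p in per_rep])
        vmaxs = np.array([p[1] for p in per_rep])
        km_sd = float(kms.std(ddof=1))
        kcat_sd = float((vmaxs / data.enzyme_conc).std(ddof=1))
    else:
        km_sd = kcat_sd = 0.0

    flags: list[str] = []
    censored = False
    s_max = float(data.substrate.max())
    if ok and km > s_max:
        # Km beyond the sampled range: no saturation observed, only a bound
        censored = True
        flags.append("km_lower_bound")
        km = s_max
        vmax = float(v_all.max()) * (km + s_max) / s_max
    kcat = vmax / data.enzyme_conc
    return MMFitResult(Km_app=km, kcat=kcat, Vmax=vmax, Km_sd=km_sd,
                       kcat_sd=kcat_sd, converged=ok, censored=censored,
                       flags=tuple(flags))


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    return float(np.round(x, -int(np.floor(np.log10(abs(x)))) + (sig - 1)))


def specificity_constant(fit: MMFitResult, sig_figs: int = 2) -> float:
    """kcat/Km_app (µM⁻¹·min⁻¹), rounded for reporting (2 sig figs)."""
    if fit.kcat == 0.0:
        return 0.0
    return _round_sig(fit.specificity, sig_figs)


@dataclass(frozen=True)
class LinearityReport:
    """Linear-range diagnostics: product vs time and velocity vs enzyme."""

    time_slope: float
    time_intercept: float
    time_r2: float
    enzyme_slope: float
    enzyme_intercept: float
    enzyme_r2: float
    max_turnover: float  # fractional consumption of the limiting substrate
    time_linear: bool
    enzyme_linear: bool
    turnover_ok: bool

    @property
    def passed(self) -> bool:
        return self.time_linear and self.enzyme_linear and self.turnover_ok


def linearity_check(time_min: NDArray[np.float64],
                    product_nM: NDArray[np.float64],
                    enzyme_nM: NDArray[np.float64],
                    velocity_nM_per_min: NDArray[np.float64],
                    limiting_substrate_nM: float,
                    r2_threshold: float = 0.98,
                    max_turnover_fraction: float = 0.10) -> LinearityReport:
    """Ordinary least squares on both series plus a turnover guard.

    Initial-rate analysis is valid only while product accumulation is
    linear in time, velocity is linear in enzyme, and consumption of the
    limiting substrate stays under 10%.
    """
    if len(time_min) < 3 or len(enzyme_nM) < 3:
        raise ValueError("need at least 3 points per series")
    t = stats.linregress(time_min, product_nM)
    e = stats.linregress(enzyme_nM, velocity_nM_per_min)
    if limiting_substrate_nM <= 0:
        raise ValueError("limiting substrate must be positive")
    turnover = float(np.max(product_nM) / limiting_substrate_nM)
    turnover = min(max(turnover, 0.0), 1.0)
    return LinearityReport(
        time_slope=float(t.slope), time_intercept=float(t.intercept),
        time_r2=float(t.rvalue ** 2),
        enzyme_slope=float(e.slope), enzyme_intercept=float(e.intercept),
        enzyme_r2=float(e.rvalue ** 2),
        max_turnover=turnover,
        time_linear=bool(t.rvalue ** 2 >= r2_threshold),
        enzyme_linear=bool(e.rvalue ** 2 >= r2_threshold),
        turnover_ok=bool(turnover < max_turnover_fraction))


def mm_result_to_dict(fit: MMFitResult) -> dict:
    """JSON-ready summary mirroring a kinetics results table row."""
    return {
        "Km_app_uM": fit.Km_app,
        "Km_sd_uM": fit.Km_sd,
        "kcat_per_min": fit.kcat,
        "kcat_sd_per_min": fit.kcat_sd,
        "Vmax_nM_per_min": fit.Vmax,
        "specificity_per_uM_per_min": specificity_constant(fit),
        "censored": fit.censored,
        "converged": fit.converged,
        "flags": list(fit.flags),
    }


__all__ = ["MMFitResult", "LinearityReport", "fit_michaelis_menten",
           "specificity_constant", "linearity_check", "mm_result_to_dict",
           "michaelis_menten_velocity"]
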