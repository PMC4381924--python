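"""Synthetic reference spectra for the two donor–acceptor pairs.

No measured spectra ship with this package. The emission and extinction
curves built here are *synthetic* skew-normal approximations to the
published band shapes of mTurquoise, EYFP and mCherry (peak positions,
widths and extinction maxima from commonly tabulated values). They are
adequate for exercising the unmixing, Förster-radius and rendering
machinery; quantitative Förster radii from real spectra require the user's
own reference CSVs via :class:`~memfret.photophysics.Spectrum.from_csv`.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .photophysics import BleedthroughCoefficients, FluorophorePair, Spectrum

SPECTRAL_GRID = np.arange(450.0, 601.0, 1.0)
"""Default detection grid: 450–600 nm at 1 nm."""


def _skew_band(grid: np.ndarray, peak_nm: float, width_nm: float,
               skew: float) -> np.ndarray:
    """Unit-peak skew-normal band; positive skew gives a red tail."""
    x = (grid - peak_nm) / width_nm
    band = norm.pdf(x) * norm.cdf(skew * x)
    top = band.max()
    return band / top if top > 0 else band


def emission_spectrum(peak_nm: float, width_nm: float = 18.0,
                      skew: float = 3.0,
                      grid: np.ndarray | None = None) -> Spectrum:
    """Synthetic unit-peak emission band with a red vibronic tail."""
    g = SPECTRAL_GRID if grid is None else np.asarray(grid, dtype=float)
    return Spectrum(g, _skew_band(g, peak_nm, width_nm, skew))


def extinction_spectrum(peak_nm: float, eps_max: float,
                        width_nm: float = 16.0, skew: float = -3.0,
                        grid: np.ndarray | None = None) -> Spectrum:
    """Synthetic extinction band (M⁻¹cm⁻¹) with a blue shoulder."""
    g = SPECTRAL_GRID if grid is None else np.asarray(grid, dtype=float)
    return Spectrum(g, eps_max * _skew_band(g, peak_nm, width_nm, skew))


def mturquoise_eyfp_pair() -> FluorophorePair:
    """Synthetic mTurquoise (donor) / EYFP (acceptor) pair on 450–600 nm.

    Quantum yields 0.84 / 0.61 and an EYFP extinction maximum of
    83,400 M⁻¹cm⁻¹ at 513 nm are standard tabulated values; spectra are
    synthetic band shapes (module docstring).
    """
    donor_em = emission_spectrum(474.0, width_nm=22.0, skew=3.5)
    acc_em = emission_spectrum(527.0, width_nm=14.0, skew=3.5)
    acc_ext = extinction_spectrum(513.0, 83400.0, width_nm=14.0, skew=-3.0)
    return FluorophorePair.from_spectra(
        "mTurquoise", "EYFP", Q_D=0.84, Q_A=0.61,
        donor_emission=donor_em, acceptor_emission=acc_em,
        acceptor_extinction=acc_ext,
        bleedthrough=BleedthroughCoefficients(0.12, 0.08))


def eyfp_mcherry_pair() -> FluorophorePair:
    """Synthetic EYFP (donor) / mCherry (acceptor) pair for vesicle imaging.

    Quantum yields 0.61 / 0.22; mCherry extinction maximum
    72,000 M⁻¹cm⁻¹ at 587 nm. Spectra span 450–700 nm so the mCherry
    emission band (~610 nm) is fully covered.
    """
    grid = np.arange(450.0, 701.0, 1.0)
    donor_em = emission_spectrum(527.0, width_nm=16.0, skew=4.0, grid=grid)
    acc_em = emission_spectrum(610.0, width_nm=22.0, skew=3.0, grid=grid)
    # mCherry absorption is broad with a pronounced blue shoulder
    acc_ext = extinction_spectrum(587.0, 72000.0, width_nm=30.0, skew=-2.5,
                                  grid=grid)
    return FluorophorePair.from_spectra(
        "EYFP", "mCherry", Q_D=0.61, Q_A=0.22,
        donor_emission=donor_em, acceptor_emission=acc_em,
        acceptor_extinction=acc_ext,
        bleedthrough=BleedthroughCoefficients(0.12, 0.08))
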