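"""Closed-form FRET math: efficiencies, Förster radius, proximity model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memfret.photophysics import (A_PER_UM, NoSpectralOverlapError,
                                  Spectrum, SpectralUnmixResult,
                                  UndefinedPixelError,
                                  apparent_efficiency_spectral,
                                  donor_quenching_efficiency,
                                  donor_transfer_sums, forster_radius,
                                  pairwise_efficiency, proximity_fret_mc,
                                  proximity_fret_low_density,
                                  reconstruct_unquenched_donor,
                                  separation_for_efficiency)


_TOY_PAIR = None


def _module_toy_pair():
    """Equal-yield toy pair for property tests (built once)."""
    global _TOY_PAIR
    if _TOY_PAIR is None:
        from memfret.photophysics import (BleedthroughCoefficients,
                                          FluorophorePair)
        wl = np.arange(450.0, 601.0, 1.0)
        donor = Spectrum(wl, np.exp(-0.5 * ((wl - 480.0) / 15.0) ** 2))
        acceptor = Spectrum(wl, np.exp(-0.5 * ((wl - 560.0) / 15.0) ** 2))
        ext = Spectrum(wl, 5e4 * np.exp(-0.5 * ((wl - 530.0) / 15.0) ** 2))
        _TOY_PAIR = FluorophorePair.from_spectra(
            "toyD", "toyA", Q_D=0.5, Q_A=0.5, donor_emission=donor,
            acceptor_emission=acceptor, acceptor_extinction=ext,
            bleedthrough=BleedthroughCoefficients(0.0, 0.0))
    return _TOY_PAIR


class TestPairwiseEfficiency:
    @pytest.mark.parametrize("r, R0, expected", [
        (54.5, 54.5, 0.5),          # r = R0 symmetry point
        (0.0, 53.1, 1.0),           # contact limit
        (2 * 53.1, 53.1, 1 / 65),   # sixth-power falloff
    ])
    def test_reference_points(self, r, R0, expected):
        assert pairwise_efficiency(r, R0) == pytest.approx(expected,
                                                           abs=1e-12)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            pairwise_efficiency(10.0, 0.0)
        with pytest.raises(ValueError):
            pairwise_efficiency(-1.0, 50.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.01, 500.0), st.floats(0.01, 500.0))
    def test_strictly_decreasing_onto_unit_interval(self, r1, r2):
        lo, hi = sorted((r1, r2))
        e_lo = pairwise_efficiency(lo, 55.0)
        e_hi = pairwise_efficiency(hi, 55.0)
        assert 0.0 < e_hi <= e_lo <= 1.0
        if hi > lo:
            assert e_hi < e_lo

    def test_separation_inverts_efficiency(self):
        for e in (0.1, 0.38, 0.9):
            r = separation_for_efficiency(e, 53.1)
            assert pairwise_efficiency(r, 53.1) == pytest.approx(e)


class TestForsterRadius:
    def _rect(self, lo, hi, value, pad=0.0):
        wl = np.linspace(lo - pad, hi + pad, 200)
        vals = np.where((wl >= lo) & (wl <= hi), value, 0.0)
        return Spectrum(wl, vals)

    def test_rectangular_toy_matches_direct_integration(self):
        # oracle: direct trapezoidal evaluation of the overlap integral and
        # the sixth root, computed independently of the implementation
        donor = self._rect(500.0, 510.0, 1.0)
        ext = self._rect(500.0, 510.0, 1e5)
        wl = np.linspace(500.0, 510.0, 2001)
        J = np.trapezoid(1.0 * 1e5 * wl ** 4, wl) / np.trapezoid(
            np.ones_like(wl), wl)
        expected = 0.211 * ((2.0 / 3.0) * 1.33 ** -4 * 0.5 * J) ** (1 / 6)
        got = forster_radius(donor, ext, Q_D=0.5)
        assert got == pytest.approx(expected, rel=1e-3)

    def test_sixth_root_quantum_yield_scaling(self):
        donor = self._rect(500.0, 510.0, 1.0)
        ext = self._rect(500.0, 510.0, 1e5)
        r_small = forster_radius(donor, ext, Q_D=0.01)
        r_big = forster_radius(donor, ext, Q_D=0.64)
        assert r_big / r_small == pytest.approx(2.0, rel=1e-9)

    def test_invariant_to_donor_rescaling(self):
        donor = self._rect(495.0, 520.0, 1.0)
        ext = self._rect(505.0, 540.0, 8e4)
        scaled = Spectrum(donor.wavelengths, donor.values * 37.5)
        assert forster_radius(donor, ext, 0.6) == pytest.approx(
            forster_radius(scaled, ext, 0.6), rel=1e-12)

    def test_disjoint_spectra_raise(self):
        donor = self._rect(460.0, 480.0, 1.0)
        ext = self._rect(560.0, 580.0, 1e5)
        with pytest.raises(NoSpectralOverlapError):
            forster_radius(donor, ext, 0.5)

    def test_published_pairs_land_in_plausible_window(self, spectral_pair,
                                                      vesicle_pair):
        # synthetic band shapes should reproduce the ~53-55 Å radii typical
        # of cyan/yellow and yellow/red fluorescent-protein pairs
        assert 45.0 < spectral_pair.R0 < 65.0
        assert 45.0 < vesicle_pair.R0 < 65.0


class TestApparentEfficiencySpectral:
    def test_limits_and_symmetric_case(self, toy_pair):
        assert apparent_efficiency_spectral(
            SpectralUnmixResult(0.0, 10.0), toy_pair) == 1.0
        assert apparent_efficiency_spectral(
            SpectralUnmixResult(10.0, 0.0), toy_pair) == 0.0
        # equal yields, equal spectral integrals, equal amplitudes -> 1/2
        w_ratio = toy_pair.w_D / toy_pair.w_A
        res = apparent_efficiency_spectral(
            SpectralUnmixResult(1.0, w_ratio), toy_pair)
        assert res == pytest.approx(0.5, rel=1e-12)

    def test_monotone_in_amplitudes(self, spectral_pair):
        base = apparent_efficiency_spectral(
            SpectralUnmixResult(100.0, 50.0), spectral_pair)
        more_acceptor = apparent_efficiency_spectral(
            SpectralUnmixResult(100.0, 80.0), spectral_pair)
        more_donor = apparent_efficiency_spectral(
            SpectralUnmixResult(160.0, 50.0), spectral_pair)
        assert more_acceptor > base > more_donor

    def test_dark_pixel_rejected(self, spectral_pair):
        with pytest.raises(UndefinedPixelError):
            apparent_efficiency_spectral(SpectralUnmixResult(0.0, 0.0),
                                         spectral_pair)


class TestDonorQuenching:
    @pytest.mark.parametrize("idm, idcorr, expected", [
        (100.0, 100.0, 0.0),
        (0.0, 50.0, 1.0),
        (50.0, 100.0, 0.5),
    ])
    def test_reference_points(self, idm, idcorr, expected):
        assert donor_quenching_efficiency(idm, idcorr) == pytest.approx(
            expected)

    def test_noise_negatives_returned_not_clipped(self):
        assert donor_quenching_efficiency(102.0, 100.0) == pytest.approx(
            -0.02)

    def test_reconstruction_bookkeeping(self, toy_pair):
        # Q_D = Q_A and unit gain ratio: counts add directly
        assert reconstruct_unquenched_donor(60.0, 40.0, toy_pair) == 100.0
        assert reconstruct_unquenched_donor(60.0, 0.0, toy_pair) == 60.0
        eapp = donor_quenching_efficiency(
            60.0, reconstruct_unquenched_donor(60.0, 40.0, toy_pair))
        assert eapp == pytest.approx(0.4)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(0.0, 0.99), st.floats(1.0, 1e5))
    def test_roundtrip_recovers_any_efficiency(self, e, total):
        pair = _module_toy_pair()
        i_dm = total * (1.0 - e)
        f_sens = total * e
        i_corr = reconstruct_unquenched_donor(i_dm, f_sens, pair)
        assert donor_quenching_efficiency(i_dm, i_corr) == pytest.approx(
            e, abs=1e-9)


class TestProximityFret:
    R0 = 55.0

    def test_no_acceptors_no_fret(self):
        est = proximity_fret_mc(100.0, 0.0, self.R0, n_realizations=5,
                                seed=0)
        assert est.E_proximity == 0.0
        assert proximity_fret_low_density(0.0, self.R0) == 0.0

    def test_fixed_coordinates_match_brute_force(self):
        # 1 donor + 2 acceptors in a periodic box: hand-computed S/(1+S)
        box = 1.0
        donor = np.array([[0.5, 0.5]])
        acc = np.array([[0.5 + 40.0 / A_PER_UM, 0.5],
                        [0.5, 0.5 - 70.0 / A_PER_UM]])
        S = donor_transfer_sums(donor, acc, self.R0 / A_PER_UM,
                                box_side=box)
        s_expected = (self.R0 / 40.0) ** 6 + (self.R0 / 70.0) ** 6
        assert S[0] == pytest.approx(s_expected, rel=1e-9)
        assert S[0] / (1 + S[0]) == pytest.approx(
            s_expected / (1 + s_expected), rel=1e-9)

    def test_minimum_image_convention(self):
        # acceptor across the periodic boundary is a near neighbour
        box = 0.5
        donor = np.array([[0.01, 0.25]])
        acc = np.array([[0.49, 0.25]])  # 0.02 µm away through the boundary
        S = donor_transfer_sums(donor, acc, self.R0 / A_PER_UM,
                                box_side=box)
        assert S[0] == pytest.approx((self.R0 / (0.02 * A_PER_UM)) ** 6,
                                     rel=1e-9)

    def test_reproducible_and_monotone_in_acceptor_density(self):
        a = proximity_fret_mc(200.0, 300.0, self.R0, n_realizations=40,
                              seed=11)
        b = proximity_fret_mc(200.0, 300.0, self.R0, n_realizations=40,
                              seed=11)
        assert a.E_proximity == b.E_proximity  # bit-for-bit
        c = proximity_fret_mc(200.0, 900.0, self.R0, n_realizations=40,
                              seed=11)
        assert c.E_proximity > a.E_proximity

    def test_closed_form_agrees_with_monte_carlo(self):
        # reduced density 0.05 with a 10 Å hard core
        sigma_a = 0.05 / (np.pi * (self.R0 / A_PER_UM) ** 2)
        mc = proximity_fret_mc(sigma_a, sigma_a, self.R0, r_exclusion=10.0,
                               n_realizations=1500, seed=42)
        cf = proximity_fret_low_density(sigma_a, self.R0, r_exclusion=10.0)
        assert abs(mc.E_proximity - cf) < 3.0 * mc.mc_stderr

    def test_large_exclusion_kills_proximity(self):
        val = proximity_fret_low_density(50.0, self.R0,
                                         r_exclusion=10 * self.R0)
        assert val < 1e-5

    def test_density_window_enforced(self):
        sigma_a = 0.5 / (np.pi * (self.R0 / A_PER_UM) ** 2)
        with pytest.raises(ValueError):
            proximity_fret_low_density(sigma_a, self.R0)

    def test_mixture_correction_reduces_to_monomer_at_p_zero(self):
        kw = dict(n_realizations=30, seed=5, r_exclusion=55.0)
        mono = proximity_fret_mc(300.0, 300.0, self.R0, **kw)
        mixed = proximity_fret_mc(300.0, 300.0, self.R0, p_partner=0.0,
                                  E_partner=0.38, **kw)
        assert mono.E_proximity == mixed.E_proximity
        # a dimerized population gains less from random neighbours
        dim = proximity_fret_mc(300.0, 300.0, self.R0, p_partner=1.0,
                                E_partner=0.38, **kw)
        assert dim.E_proximity < mono.E_proximity
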