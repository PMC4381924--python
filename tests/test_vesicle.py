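"""Vesicle pipeline: detection, profile fits, corrections, quantitation."""

import numpy as np
import pytest

from memfret.photophysics import BleedthroughCoefficients
from memfret.synthetic import (OpticsParams, SceneParams,
                               render_vesicle_images, scene_for_vesicle)
from memfret.vesicle import (ConcentrationCalibration, MeasurementConfig,
                             calibrate_concentration, correct_bleedthrough,
                             detect_vesicles, estimate_bleedthrough,
                             fit_membrane_profile, measure_image_set,
                             measure_vesicle, _profile_model)


def _render(pair, total_density=1000.0, x_a=0.5, seed=5, noise=True,
            radius=3.0, Kd2d=150.0, E_dimer=0.38, **optics_kw):
    opt = OpticsParams(vesicle_radius=radius, **optics_kw)
    params = SceneParams(total_density=total_density, x_a_true=x_a,
                         Kd2d=Kd2d, E_dimer=E_dimer, seed=seed)
    scene = scene_for_vesicle(params, opt, R0=pair.R0)
    return scene, render_vesicle_images(scene, opt, pair, seed=seed + 1,
                                        noise=noise)


class TestDetection:
    def test_single_vesicle_found_precisely(self, vesicle_pair):
        _, ims = _render(vesicle_pair, noise=True)
        boundaries, _ = detect_vesicles(ims)
        assert len(boundaries) == 1
        b = boundaries[0]
        cx, cy = ims.optics.center_px()
        assert abs(b.center[0] - cx) < 1.0 and abs(b.center[1] - cy) < 1.0
        assert b.radius == pytest.approx(3.0, rel=0.02)
        assert b.present_in_all_scans

    def test_background_only_image_yields_nothing(self, vesicle_pair):
        _, ims = _render(vesicle_pair, total_density=0.0)
        boundaries, _ = detect_vesicles(ims)
        assert boundaries == []

    def test_vesicle_missing_from_acceptor_scan_rejected(self, toy_pair):
        # acceptor-free scene: the acceptor scan carries no membrane signal
        _, ims = _render(toy_pair, x_a=0.0)
        boundaries, log = detect_vesicles(ims)
        assert boundaries == []
        assert any("absent from acceptor scan" in line for line in log)


class TestMembraneProfileFit:
    TRUE = dict(A=120.0, d0=0.03, sigma=0.21, B=-18.0, C=28.0, sigma_b=0.24)

    def test_noise_free_parameter_recovery(self):
        d = np.linspace(-1.0, 1.0, 161)
        y = _profile_model(d, *self.TRUE.values())
        fit = fit_membrane_profile(d, y)
        assert fit.converged
        assert fit.amplitude == pytest.approx(self.TRUE["A"], rel=1e-6)
        assert fit.center == pytest.approx(self.TRUE["d0"], abs=1e-6)
        assert fit.sigma == pytest.approx(self.TRUE["sigma"], rel=1e-6)
        assert fit.step_height == pytest.approx(self.TRUE["B"], rel=1e-5)
        assert fit.offset == pytest.approx(self.TRUE["C"], rel=1e-6)

    def test_membrane_integral_is_gaussian_area(self):
        d = np.linspace(-1.0, 1.0, 161)
        y = _profile_model(d, 50.0, 0.0, 0.2, 0.0, 5.0, 0.2)
        fit = fit_membrane_profile(d, y)
        assert fit.membrane_integral == pytest.approx(
            50.0 * 0.2 * np.sqrt(2 * np.pi), rel=1e-6)

    def test_flat_profile_reports_zero_amplitude(self):
        d = np.linspace(-1.0, 1.0, 161)
        y = np.full_like(d, 20.0)
        fit = fit_membrane_profile(d, y)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-6)


class TestBleedthrough:
    def test_zero_coefficients_identity(self):
        f, flags = correct_bleedthrough(100.0, 50.0, 30.0,
                                        BleedthroughCoefficients(0.0, 0.0))
        assert f == 30.0 and flags == []

    def test_linear_roundtrip(self):
        coeffs = BleedthroughCoefficients(0.12, 0.08)
        i_dm, i_am, f_true = 200.0, 150.0, 40.0
        raw = f_true + 0.12 * i_dm + 0.08 * i_am
        f, _ = correct_bleedthrough(i_dm, i_am, raw, coeffs)
        assert f == pytest.approx(f_true, rel=1e-12)

    def test_negative_correction_flagged_not_clipped(self):
        f, flags = correct_bleedthrough(100.0, 100.0, 5.0,
                                        BleedthroughCoefficients(0.12, 0.08))
        assert f < 0 and "negative_sensitized_emission" in flags

    def test_estimated_from_donor_only_standard(self, vesicle_pair):
        # donor-only scene rendered with the pair's true 0.12 coefficient
        _, ims = _render(vesicle_pair, x_a=0.0, total_density=1500.0,
                         seed=8)
        coeffs = estimate_bleedthrough(donor_standard=ims)
        assert coeffs.donor_into_fret == pytest.approx(0.12, abs=0.005)
        assert coeffs.acceptor_direct_excitation == 0.0

    def test_estimate_invariant_to_intensity_scale(self, vesicle_pair):
        _, dim = _render(vesicle_pair, x_a=0.0, total_density=400.0,
                         seed=9)
        _, bright = _render(vesicle_pair, x_a=0.0, total_density=1600.0,
                            seed=9)
        c_dim = estimate_bleedthrough(donor_standard=dim)
        c_bright = estimate_bleedthrough(donor_standard=bright)
        assert c_dim.donor_into_fret == pytest.approx(
            c_bright.donor_into_fret, abs=0.01)


class TestCalibration:
    def test_slope_semantics(self):
        calib = ConcentrationCalibration(slope_donor=10.0,
                                         slope_acceptor=5.0)
        assert calibrate_concentration(0.0, calib.slope_donor) == 0.0
        assert calibrate_concentration(100.0, 10.0) == 10.0
        assert calibrate_concentration(100.0, 20.0) == 5.0

    def test_rejects_non_positive_slopes(self):
        with pytest.raises(ValueError):
            ConcentrationCalibration(slope_donor=0.0, slope_acceptor=1.0)


class TestMeasureVesicle:
    def test_noise_free_roundtrip(self, noise_free_vesicle, vesicle_pair):
        scene, ims = noise_free_vesicle
        gt = ims.ground_truth
        ms, log = measure_image_set(ims, vesicle_pair)
        assert len(ms) == 1, log
        m = ms[0]
        assert m.Eapp == pytest.approx(gt.mean_Eapp, abs=1e-3)
        assert m.sigma_D == pytest.approx(gt.sigma_D, rel=0.01)
        assert m.sigma_A == pytest.approx(gt.sigma_A, rel=0.01)

    def test_acceptor_free_scene_zero_fret_and_xa(self, toy_pair):
        # bypass the presence QC (which would reject the empty acceptor
        # scan) and quantify against the true boundary directly
        _, ims = _render(toy_pair, x_a=0.0, noise=False)
        from memfret.vesicle import VesicleBoundary
        cx, cy = ims.optics.center_px()
        b = VesicleBoundary(center=(cx, cy), radius=3.0, circularity=1.0,
                            present_in_all_scans=True)
        calib = ConcentrationCalibration.from_optics(ims.optics, toy_pair)
        m = measure_vesicle(ims, b, toy_pair, toy_pair.bleedthrough, calib)
        assert abs(m.Eapp) < 1e-3
        assert m.x_a == pytest.approx(0.0, abs=1e-3)

    def test_saturated_dimer_apparent_fret_is_xa_scaled(self, vesicle_pair):
        # constitutive dimer at Ẽ = 0.38, proximity off: Eapp = x_a·Ẽ
        opt = OpticsParams(vesicle_radius=3.0)
        params = SceneParams(total_density=800.0, x_a_true=0.5, Kd2d=1e-6,
                             E_dimer=0.38, seed=21)
        scene = scene_for_vesicle(params, opt, R0=vesicle_pair.R0)
        ims = render_vesicle_images(scene, opt, vesicle_pair, noise=False,
                                    include_proximity=False)
        ms, _ = measure_image_set(ims, vesicle_pair)
        m = ms[0]
        assert m.Eapp == pytest.approx(m.x_a * 0.38, abs=1e-3)

    def test_mean_xa_matches_labeling_fraction(self, vesicle_pair):
        xs = []
        for seed in range(25):
            _, ims = _render(vesicle_pair, total_density=800.0, seed=seed)
            ms, _ = measure_image_set(ims, vesicle_pair)
            xs.extend(m.x_a for m in ms)
        assert np.mean(xs) == pytest.approx(0.5, abs=0.01)

    def test_density_regression_slope_near_unity(self, vesicle_pair):
        # noisy vesicles spanning the full expression range: measured vs
        # true total density regresses with slope 1 and high R²
        rng = np.random.default_rng(0)
        true, meas = [], []
        for i in range(60):
            dens = float(np.exp(rng.uniform(np.log(100), np.log(2000))))
            scene, ims = _render(vesicle_pair, total_density=dens,
                                 seed=1000 + i)
            ms, _ = measure_image_set(ims, vesicle_pair)
            if ms:
                true.append(scene.sigma_D + scene.sigma_A)
                meas.append(ms[0].total_density)
        assert len(true) > 45
        slope, intercept = np.polyfit(true, meas, 1)
        pred = slope * np.asarray(true) + intercept
        resid = np.asarray(meas) - pred
        r2 = 1 - resid.var() / np.var(meas)
        assert slope == pytest.approx(1.0, abs=0.05)
        assert r2 > 0.95

    def test_exclusion_of_one_vesicle_is_logged_with_reason(self,
                                                            vesicle_pair):
        _, ims = _render(vesicle_pair, total_density=1000.0, seed=3)
        strict = MeasurementConfig(min_profile_r2=0.999999)
        ms, log = measure_image_set(ims, vesicle_pair, config=strict)
        assert ms == []
        assert any("excluded" in line for line in log)
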