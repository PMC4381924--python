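"""Generators: equilibrium solver, scenes, renders, kinetics data."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from memfret.photophysics import A_PER_UM
from memfret.synthetic import (ACCEPTOR, DARK, DONOR, OpticsParams,
                               SceneParams, generate_mm_dataset,
                               generate_scene, michaelis_menten_velocity,
                               render_spectral_image, render_vesicle_images,
                               scene_donor_efficiencies, scene_for_vesicle,
                               solve_dimer_equilibrium, spectral_amplitudes,
                               truncated_normal_field)

R0 = 55.0


class TestDimerEquilibrium:
    def test_all_monomer_and_all_dimer_limits(self):
        _, _, frac_mono = solve_dimer_equilibrium(100.0, 1e9 * 100.0)
        assert frac_mono < 1e-6
        _, _, frac_dim = solve_dimer_equilibrium(100.0, 1e-9 * 100.0)
        assert frac_dim > 1 - 1e-3

    def test_half_dimerized_at_t_equals_kd(self):
        # closed form cross-checked against a numeric root of the
        # mass-action system Kd = (T-2D)^2 / D
        M, D, frac = solve_dimer_equilibrium(150.0, 150.0)
        assert frac == pytest.approx(0.5, rel=1e-12)
        assert M == pytest.approx(75.0) and D == pytest.approx(37.5)
        d_oracle = brentq(lambda d: (150.0 - 2 * d) ** 2 / d - 150.0,
                          1e-9, 74.999)
        assert D == pytest.approx(d_oracle, rel=1e-9)

    def test_zero_density(self):
        assert solve_dimer_equilibrium(0.0, 10.0) == (0.0, 0.0, 0.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.floats(1e-3, 1e5), st.floats(1e-3, 1e5))
    def test_mass_conservation_and_kd_consistency(self, total, kd):
        M, D, frac = solve_dimer_equilibrium(total, kd)
        assert M >= 0 and D >= 0
        assert M + 2 * D == pytest.approx(total, rel=1e-12)
        assert M * M / D == pytest.approx(kd, rel=1e-9)
        assert frac == pytest.approx(2 * D / total, rel=1e-12)


class TestGenerateScene:
    def _params(self, **kw):
        base = dict(total_density=500.0, x_a_true=0.5, Kd2d=150.0,
                    E_dimer=0.38, area=25.0, seed=1)
        base.update(kw)
        return SceneParams(**base)

    def test_no_acceptors_when_unlabeled(self):
        scene = generate_scene(self._params(x_a_true=0.0), R0=R0)
        assert np.sum(scene.labels == ACCEPTOR) == 0

    def test_deterministic_under_seed(self):
        a = generate_scene(self._params(), R0=R0)
        b = generate_scene(self._params(), R0=R0)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.labels, b.labels)

    def test_fully_dimeric_partners_at_configured_separation(self):
        scene = generate_scene(self._params(Kd2d=1e-6, x_a_true=1.0), R0=R0)
        sep = scene.params.separation(R0) / A_PER_UM
        olig = scene.oligomer_ids
        lx, ly = scene.extent
        ids, counts = np.unique(olig, return_counts=True)
        assert (counts == 2).all()
        for oid in ids[:50]:
            a, b = scene.positions[olig == oid]
            d = a - b
            d -= np.round(d / (lx, ly)) * (lx, ly)
            assert np.hypot(*d) == pytest.approx(sep, abs=1e-6 * 1e-3)

    def test_realized_density_matches_poisson_expectation(self):
        dens = []
        for seed in range(300):
            scene = generate_scene(self._params(seed=seed,
                                                dark_fraction=0.2), R0=R0)
            dens.append((scene.sigma_D + scene.sigma_A))
        expected = 0.8 * 500.0
        sem = np.std(dens, ddof=1) / np.sqrt(len(dens))
        assert abs(np.mean(dens) - expected) < 3 * sem

    def test_dark_molecules_occupy_dimer_slots_silently(self):
        scene = generate_scene(self._params(Kd2d=1e-6, dark_fraction=0.5),
                               R0=R0)
        assert np.sum(scene.labels == DARK) > 0
        # dimer pairing unaffected by darkness
        _, counts = np.unique(scene.oligomer_ids, return_counts=True)
        assert (counts == 2).all()


class TestSceneEfficiencies:
    def test_saturated_dimer_without_proximity_is_pairwise_value(self):
        params = SceneParams(total_density=400.0, x_a_true=1.0, Kd2d=1e-6,
                             E_dimer=0.38, area=25.0, seed=3)
        scene = generate_scene(params, R0=R0)
        # all-acceptor scene has no donors; relabel half deterministically
        rng = np.random.default_rng(0)
        flip = rng.uniform(size=len(scene.labels)) < 0.5
        scene.labels[flip] = DONOR
        E = scene_donor_efficiencies(scene, R0, include_proximity=False)
        donors = scene.labels == DONOR
        olig = scene.oligomer_ids
        partner_acc = []
        for i in np.flatnonzero(donors):
            mates = np.flatnonzero((olig == olig[i])
                                   & (np.arange(len(olig)) != i))
            partner_acc.append(scene.labels[mates[0]] == ACCEPTOR)
        partner_acc = np.array(partner_acc)
        assert E[partner_acc] == pytest.approx(0.38, abs=1e-9)
        assert E[~partner_acc] == pytest.approx(0.0, abs=1e-12)

    def test_mean_efficiency_tracks_dimer_fraction_times_xa(self):
        # proximity disabled: scene mean per-donor E = f·x_a·Ẽ up to
        # labeling/pairing sampling error, averaged over seeds
        vals, preds = [], []
        for seed in range(120):
            params = SceneParams(total_density=600.0, x_a_true=0.4,
                                 Kd2d=200.0, E_dimer=0.38, area=25.0,
                                 seed=seed)
            scene = generate_scene(params, R0=R0)
            E = scene_donor_efficiencies(scene, R0,
                                         include_proximity=False)
            if len(E):
                vals.append(E.mean())
                preds.append(scene.realized_dimer_fraction * 0.4 * 0.38)
        err = np.array(vals) - np.array(preds)
        assert abs(err.mean()) < 3 * err.std(ddof=1) / np.sqrt(len(err))


class TestVesicleRender:
    def test_empty_scene_gives_background_only(self, vesicle_pair):
        opt = OpticsParams(vesicle_radius=3.0)
        params = SceneParams(total_density=0.0, x_a_true=0.5, Kd2d=150.0,
                             E_dimer=0.38, seed=0)
        scene = scene_for_vesicle(params, opt, R0=vesicle_pair.R0)
        ims = render_vesicle_images(scene, opt, vesicle_pair, noise=False)
        interior = ims.donor_scan[64, 64]
        assert interior == pytest.approx(opt.background_interior, abs=1e-9)
        assert ims.donor_scan.max() <= opt.background_interior + 1e-9

    def test_no_acceptors_no_crosstalk_fret_scan_is_background(self,
                                                               toy_pair):
        opt = OpticsParams(vesicle_radius=3.0)
        params = SceneParams(total_density=500.0, x_a_true=0.0, Kd2d=150.0,
                             E_dimer=0.38, seed=2)
        scene = scene_for_vesicle(params, opt, R0=toy_pair.R0)
        ims = render_vesicle_images(scene, opt, toy_pair, noise=False)
        bg_only = np.ptp(ims.fret_scan) == pytest.approx(
            opt.background_interior - opt.background_exterior, abs=1e-9)
        assert bg_only
        assert ims.donor_scan.max() > ims.fret_scan.max()

    def test_photon_conservation_pixelwise(self, toy_pair):
        # every dimer relabeled donor+acceptor: all donors transfer at the
        # pairwise efficiency, so at every pixel the quenched donor counts
        # plus the yield/gain-scaled sensitized counts reproduce the
        # unquenched donor counts: I_D = (1-E)·(I_D + c·F_sens) exactly
        e_dim = 0.38
        opt = OpticsParams(vesicle_radius=3.0, background_interior=0.0,
                           background_exterior=0.0)
        params = SceneParams(total_density=800.0, x_a_true=0.5, Kd2d=1e-9,
                             E_dimer=e_dim, seed=4)
        scene = scene_for_vesicle(params, opt, R0=toy_pair.R0)
        for oid in np.unique(scene.oligomer_ids):
            members = np.flatnonzero(scene.oligomer_ids == oid)
            scene.labels[members[0]] = DONOR
            scene.labels[members[1]] = ACCEPTOR
        ims = render_vesicle_images(scene, opt, toy_pair, noise=False,
                                    include_proximity=False)
        c = (toy_pair.Q_D / toy_pair.Q_A) * opt.gain_ratio
        unquenched = ims.donor_scan + c * ims.fret_scan
        signal = unquenched > 1e-6 * unquenched.max()
        ratio = ims.donor_scan[signal] / unquenched[signal]
        assert ratio == pytest.approx(1.0 - e_dim, rel=1e-9)

    def test_render_reproducible(self, vesicle_pair, noise_free_vesicle):
        scene, _ = noise_free_vesicle
        opt = OpticsParams(vesicle_radius=3.0)
        a = render_vesicle_images(scene, opt, vesicle_pair, seed=9)
        b = render_vesicle_images(scene, opt, vesicle_pair, seed=9)
        assert np.array_equal(a.donor_scan, b.donor_scan)
        assert np.array_equal(a.fret_scan, b.fret_scan)


class TestSpectralRender:
    def test_zero_efficiency_pixels_are_pure_donor(self, spectral_pair):
        E = np.zeros((4, 4))
        T = np.full((4, 4), 1000.0)
        img = render_spectral_image(E, T, spectral_pair,
                                    poisson_noise=False)
        ref = spectral_pair.donor_emission.values
        spec = img.stack[:, 0, 0]
        assert spec == pytest.approx(spec.max() * ref / ref.max(), abs=1e-9)

    def test_intensity_scaling_leaves_amplitude_ratio_fixed(self,
                                                            spectral_pair):
        E = np.array([[0.3]])
        k1 = spectral_amplitudes(E, np.array([[1000.0]]), spectral_pair)
        k2 = spectral_amplitudes(E, np.array([[2000.0]]), spectral_pair)
        assert k2[0] == pytest.approx(2 * k1[0])
        assert k2[1] == pytest.approx(2 * k1[1])

    def test_truncated_field_respects_bounds_and_moments(self):
        field = truncated_normal_field(0.21, 0.13, (20000,), seed=0)
        assert field.min() >= 0.0 and field.max() <= 1.0
        # analytic mean of the truncated normal
        from scipy.stats import truncnorm
        a, b = (0 - 0.21) / 0.13, (1 - 0.21) / 0.13
        expected = truncnorm.mean(a, b, loc=0.21, scale=0.13)
        assert field.mean() == pytest.approx(expected, abs=0.005)


class TestMMGenerator:
    def test_half_saturation_and_plateau(self):
        data = generate_mm_dataset(89.0, 749.0, 1.0, [89.0, 8900.0],
                                   noise_cv=0.0)
        assert data.velocities[0, 0] == pytest.approx(749.0 / 2.0)
        assert data.velocities[0, 1] == pytest.approx(749.0, rel=0.01)

    def test_noise_free_replicates_identical(self):
        data = generate_mm_dataset(50.0, 100.0, 2.0, [10, 50, 200],
                                   noise_cv=0.0, n_replicates=3)
        assert np.array_equal(data.velocities[0], data.velocities[1])

    def test_lognormal_noise_has_unit_mean(self):
        data = generate_mm_dataset(50.0, 100.0, 2.0, [50.0] * 200,
                                   noise_cv=0.1, n_replicates=10, seed=3)
        v_true = michaelis_menten_velocity(50.0, 50.0, 100.0, 2.0)
        ratios = data.velocities / v_true
        assert ratios.mean() == pytest.approx(1.0, abs=0.01)
        assert ratios.std() == pytest.approx(0.1, abs=0.02)

    def test_csv_roundtrip(self, tmp_path):
        from memfret.io import read_kinetics_csv
        data = generate_mm_dataset(89.0, 749.0, 1.0,
                                   [500, 250, 125, 62.5], noise_cv=0.05,
                                   seed=9)
        path = tmp_path / "velocities.csv"
        data.to_csv(path)
        back = read_kinetics_csv(path, enzyme_nM=1.0)
        assert np.allclose(np.sort(back.substrate),
                           np.sort(data.substrate))
        assert back.velocities.shape == data.velocities.shape
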