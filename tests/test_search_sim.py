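"""First-passage target-search simulator and its analytic frame."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from tfmap import search_sim as ss


class TestConfig:
    def test_undersampling_step_rejected(self):
        with pytest.raises(ValueError, match="step S.D."):
            ss.SimConfig(dt_s=0.01)  # 447 nm steps vs 40 nm targets

    def test_overlapping_targets_rejected(self):
        with pytest.raises(ValueError):
            ss.SimConfig(min_separation_nm=50.0)

    def test_small_target_variant_allowed(self):
        cfg = ss.SimConfig(target_radius_nm=30.0, min_separation_nm=80.0,
                           dt_s=4e-6)
        assert cfg.step_sd_nm < 30.0

    def test_default_step_matches_stated_scale(self):
        assert ss.SimConfig().step_sd_nm == pytest.approx(14.14, abs=0.01)


class TestPlaceTargets:
    def test_uniform_targets_respect_separation(self):
        tgt = ss.place_targets(ss.DESK, seed=1)
        assert len(tgt.positions_nm) == 700
        assert pdist(tgt.positions_nm).min() >= 80.0
        assert np.linalg.norm(tgt.positions_nm, axis=1).max() <= 2000.0

    def test_clustered_targets_respect_separation(self):
        tgt = ss.place_targets(ss.DESK, seed=2, sigma_nm=200.0, n_clusters=7)
        assert pdist(tgt.positions_nm).min() >= 80.0
        assert tgt.cluster_labels is not None
        assert len(np.unique(tgt.cluster_labels)) == 7

    def test_single_target(self):
        cfg = ss.SimConfig(nucleus_radius_um=1.0, n_targets=1, dt_s=1e-5)
        tgt = ss.place_targets(cfg, seed=3)
        assert tgt.positions_nm.shape == (1, 3)


class TestReflection:
    def test_interior_points_untouched(self):
        pts = np.array([[100.0, 0, 0], [0, -500.0, 0]])
        np.testing.assert_array_equal(ss.reflect_into_sphere(pts, 1000.0), pts)

    def test_exterior_points_folded_inside(self):
        # valid domain: excursions stay below 2R (steps are tiny vs nucleus)
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 300, size=(500, 3))
        r_in = np.linalg.norm(pts, axis=1)
        pts, r_in = pts[r_in < 1400.0], r_in[r_in < 1400.0]
        out = ss.reflect_into_sphere(pts, 700.0)
        r_out = np.linalg.norm(out, axis=1)
        assert (r_out <= 700.0 + 1e-9).all()
        outside = r_in > 700.0
        assert outside.sum() > 10
        np.testing.assert_allclose(r_out[outside], 2 * 700.0 - r_in[outside])


class TestFirstPassage:
    def test_injection_next_to_target_hits_fast(self):
        cfg = ss.SimConfig(nucleus_radius_um=1.0, n_targets=1, dt_s=1e-5)
        tgt = ss.TargetSet(np.array([[0.0, 0.0, 0.0]]), cfg.target_radius_nm,
                           1000.0)
        res = ss.simulate_release(tgt, cfg, releasing_radius_nm=41.0,
                                  n_trials=50, seed=5,
                                  release_center_nm=np.zeros(3))
        assert res.n_censored == 0
        assert np.median(res.tau_s) <= 10 * cfg.dt_s

    def test_kdtree_and_bruteforce_identical(self):
        cfg = ss.SimConfig(nucleus_radius_um=1.0, n_targets=150, dt_s=2e-5,
                           min_separation_nm=80.0)
        tgt = ss.place_targets(cfg, seed=6)
        a = ss.simulate_first_passage(tgt, cfg, n_trials=25, seed=7,
                                      neighbor="kdtree")
        b = ss.simulate_first_passage(tgt, cfg, n_trials=25, seed=7,
                                      neighbor="brute")
        np.testing.assert_array_equal(a.tau_s, b.tau_s)
        np.testing.assert_array_equal(a.hit_target, b.hit_target)

    def test_dilute_uniform_matches_smoluchowski_within_factor_two(self):
        cfg = ss.SimConfig(nucleus_radius_um=2.0, n_targets=70, dt_s=2e-5,
                           max_steps=2_000_000)
        tgt = ss.place_targets(cfg, seed=8)
        res = ss.simulate_first_passage(tgt, cfg, n_trials=300, seed=9)
        tau_theory = ss.smoluchowski_tau(cfg.target_radius_nm, cfg.D_um2_s,
                                         cfg.target_density_per_um3)
        assert res.n_censored == 0
        assert 0.5 < res.mean_tau_s / tau_theory < 2.0

    def test_release_radius_outside_nucleus_rejected(self):
        tgt = ss.place_targets(ss.DESK, seed=10)
        with pytest.raises(ValueError):
            ss.simulate_release(tgt, ss.DESK, releasing_radius_nm=5000.0,
                                n_trials=5, seed=11)

    def test_survival_function_monotone(self):
        cfg = ss.DESK
        tgt = ss.place_targets(cfg, seed=12)
        res = ss.simulate_first_passage(tgt, cfg, n_trials=100, seed=13)
        t = np.sort(res.tau_s)
        surv = 1.0 - np.arange(1, t.size + 1) / t.size
        assert (np.diff(surv) <= 0).all()
        assert (res.tau_s > 0).all()


class TestFoldOfDelay:
    def test_identical_inputs_give_unity(self):
        cfg = ss.DESK
        tgt = ss.place_targets(cfg, seed=14)
        res = ss.simulate_first_passage(tgt, cfg, n_trials=80, seed=15)
        ratio, (lo, hi) = ss.fold_of_delay(res, res)
        assert ratio == 1.0
        assert lo <= 1.0 <= hi


class TestExponentialFits:
    def test_single_exponential_lifetime_recovered(self):
        rng = np.random.default_rng(16)
        tau = rng.exponential(5.0, 1000)
        fit = ss.fit_exponential(tau, k=1)
        assert fit.lifetimes_s[0] == pytest.approx(5.0, rel=0.10)

    def test_two_component_recovery(self):
        rng = np.random.default_rng(17)
        tau = np.concatenate([rng.exponential(1.0, 600),
                              rng.exponential(10.0, 400)])
        fit = ss.fit_exponential(tau, k=2)
        assert fit.k == 2
        assert fit.lifetimes_s[0] == pytest.approx(1.0, rel=0.15)
        assert fit.lifetimes_s[1] == pytest.approx(10.0, rel=0.15)
        assert fit.fast_fraction == pytest.approx(0.6, abs=0.1)

    def test_degenerate_two_component_collapses(self):
        rng = np.random.default_rng(18)
        tau = rng.exponential(4.0, 800)
        fit = ss.fit_exponential(tau, k=2)
        if fit.k == 2:  # if EM keeps two components they must beat one barely
            f1 = ss.fit_exponential(tau, k=1)
            assert ss.likelihood_ratio(f1, fit) < 9.21  # chi2_{0.99, df=2}
        else:
            assert fit.k == 1

    def test_small_sample_flagged(self):
        fit = ss.fit_exponential(np.ones(10), k=1)
        assert not fit.converged


class TestSmoluchowski:
    def test_density_scaling(self):
        t1 = ss.smoluchowski_tau(40.0, 10.0, 5.0)
        t2 = ss.smoluchowski_tau(40.0, 10.0, 10.0)
        assert t1 == pytest.approx(2 * t2)

    def test_hand_computed_reference(self):
        rho = 7000.0 / (4.0 / 3.0 * np.pi * 5.0**3)
        expected = 1.0 / (4 * np.pi * 0.04 * 10.0 * rho)
        assert ss.smoluchowski_tau(40.0, 10.0, rho) == pytest.approx(expected)
        assert expected == pytest.approx(0.0149, abs=0.0002)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ss.smoluchowski_tau(0.0, 10.0, 1.0)


class TestBrownianValidation:
    def test_assigned_D_recovered_within_five_percent(self):
        out = ss.validate_brownian(10.0, 1e-5, n_tracks=100, seed=19,
                                   track_length=100, n_repeats=2)
        assert out["D_recovered_mean"] == pytest.approx(10.0, rel=0.05)

    def test_zero_D_recovered_as_zero(self):
        out = ss.validate_brownian(0.0, 1e-5, n_tracks=10, seed=20,
                                   track_length=50, n_repeats=1)
        assert out["D_recovered_mean"] == 0.0

    def test_pooled_msd_linear(self):
        from tfmap.diffusion import msd_curve
        from tfmap.synth import gen_brownian_tracks

        ts = gen_brownian_tracks(10.0, 1e-5, 100, 100, seed=21)
        msds = np.mean([msd_curve(xyz, 1e-5, 25) for _, _, xyz in ts.iter_tracks()],
                       axis=0)
        t = np.arange(1, 26) * 1e-5
        resid = np.polyfit(t, msds, 1, full=True)[1][0]
        ss_tot = np.sum((msds - msds.mean()) ** 2)
        assert 1 - resid / ss_tot > 0.99
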