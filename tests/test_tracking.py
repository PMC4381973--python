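"""Linking, stable-site extraction, and temporal profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from tfmap import synth, tracking
from tfmap.synth import TrackSet


def _locs_from_positions(positions, n_frames, noise_sd=0.0, seed=0):
    """Localization table for immobile emitters at given 2D positions."""
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(n_frames):
        for i, (x, y) in enumerate(positions):
            rows.append((f, x + rng.normal(0, noise_sd), y + rng.normal(0, noise_sd)))
    return pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm"])


class TestLinkTracks:
    def test_distant_molecules_stay_separate(self):
        locs = _locs_from_positions([(0, 0), (5000, 5000)], n_frames=5)
        ts = tracking.link_tracks(locs, dt_s=0.5)
        assert ts.n_tracks == 2
        for _, _, xyz in ts.iter_tracks():
            assert len(xyz) == 5

    def test_default_gate_from_Dmax(self):
        # r_max = sqrt(2 d Dmax dt): 2D, Dmax 0.05 um^2/s, dt 0.5 s -> 316 nm
        assert tracking.max_link_radius_nm(0.05, 0.5, 2) == pytest.approx(316.2, abs=0.1)

    def test_linking_accuracy_on_sparse_immobile_field(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 40_000, size=(20, 2))  # ~0.0125 spots/um^2
        locs = _locs_from_positions(pos, n_frames=10, noise_sd=15, seed=4)
        ts = tracking.link_tracks(locs, dt_s=0.5)
        assert ts.n_tracks == 20
        correct = 0
        for _, _, xyz in ts.iter_tracks():
            d = np.linalg.norm(pos - xyz.mean(axis=0), axis=1)
            correct += len(xyz) if np.linalg.norm(xyz - pos[d.argmin()], axis=1).max() < 100 else 0
        assert correct / len(locs) >= 0.99

    def test_every_detection_in_exactly_one_track(self):
        locs = _locs_from_positions([(0, 0), (400, 0), (800, 0)], n_frames=4)
        ts = tracking.link_tracks(locs, dt_s=0.5)
        assert len(ts.data) == len(locs)
        assert ts.data.groupby(["frame", "track_id"]).size().max() == 1


def _immobile_trackset(n_tracks, n_frames, dt_s, noise_sd=0.0, seed=0):
    spec = synth.TrackMixtureSpec([(0.0, 1.0)], dt_s, n_tracks, n_frames,
                                  loc_noise_sd_nm=noise_sd)
    return synth.gen_mixture_tracks(spec, seed=seed)


class TestStableSites:
    def test_immobile_track_gives_one_site_with_full_residence(self):
        ts = _immobile_trackset(1, 12, dt_s=3.0)
        sites = tracking.stable_sites(ts, max_disp_nm=50, min_duration_s=3.0)
        assert len(sites) == 1
        assert sites.loc[0, "residence_s"] == pytest.approx(36.0)

    def test_single_large_step_rejected(self):
        df = pd.DataFrame({
            "track_id": 0, "frame": np.arange(8),
            "x_nm": [0, 0, 0, 60, 60, 60, 60, 60],
            "y_nm": 0.0, "z_nm": 0.0,
        })
        sites = tracking.stable_sites(TrackSet(df, 3.0), 50, 3.0)
        assert len(sites) == 0

    def test_end_to_end_bound_rejects_slow_creep(self):
        # 10 steps of 10 nm: every step passes, the end-to-end span does not
        df = pd.DataFrame({
            "track_id": 0, "frame": np.arange(11),
            "x_nm": np.arange(11) * 10.0, "y_nm": 0.0, "z_nm": 0.0,
        })
        sites = tracking.stable_sites(TrackSet(df, 3.0), 50, 3.0)
        assert len(sites) == 0

    def test_identity_limit_returns_every_track(self):
        ts = synth.gen_brownian_tracks(1.0, 0.5, 25, 6, seed=5, ndim=2)
        sites = tracking.stable_sites(ts, max_disp_nm=np.inf, min_duration_s=0.0)
        assert len(sites) == 25

    def test_site_count_monotone_in_cutoffs(self):
        ts = synth.gen_mixture_tracks(
            synth.TrackMixtureSpec([(0.0, 0.5), (0.5, 0.5)], 0.5, 60, 10,
                                   loc_noise_sd_nm=12), seed=6, ndim=3)
        n_by_duration = [len(tracking.stable_sites(ts, 50, s))
                         for s in (0.0, 2.0, 4.0, 6.0)]
        assert n_by_duration == sorted(n_by_duration, reverse=True)
        n_by_disp = [len(tracking.stable_sites(ts, d, 2.0))
                     for d in (20, 50, 100, np.inf)]
        assert n_by_disp == sorted(n_by_disp)

    def test_single_frame_policy(self):
        df = pd.DataFrame({"track_id": [0], "frame": [3],
                           "x_nm": [1.0], "y_nm": [2.0], "z_nm": [0.0]})
        ts = TrackSet(df, 0.5)
        assert len(tracking.stable_sites(ts, 50, 0.5, single_frame="discard")) == 0
        got = tracking.stable_sites(ts, 50, 0.5, single_frame="bound")
        assert len(got) == 1
        assert got.loc[0, "residence_s"] == pytest.approx(0.5)

    def test_bound_fraction_recovered_from_mixture(self):
        spec = synth.TrackMixtureSpec([(0.0, 0.64), (1.4, 0.36)], 0.5, 200, 12,
                                      loc_noise_sd_nm=10)
        ts = synth.gen_mixture_tracks(spec, seed=7, ndim=2)
        sites = tracking.stable_sites(ts, 50, 2.0, single_frame="bound")
        frac = len(sites) / ts.n_tracks
        # binomial error at n=200 plus the noise-induced step failures
        assert frac == pytest.approx(0.64, abs=0.08)


class TestProfiles:
    def test_residence_mean_at_cutoff(self):
        sites = pd.DataFrame({"residence_s": [3.0, 3.0, 3.0]})
        _, mean, sem = tracking.residence_stats(sites)
        assert mean == pytest.approx(3.0)
        assert sem == 0.0

    def test_exponential_residence_mean_recovered(self):
        rng = np.random.default_rng(8)
        sites = pd.DataFrame({"residence_s": rng.exponential(7.0, 2000)})
        _, mean, sem = tracking.residence_stats(sites)
        assert mean == pytest.approx(7.0, rel=0.10)

    def test_detections_per_frame_flat_for_constant_rate(self):
        locs = pd.DataFrame({"frame": np.repeat(np.arange(50), 4),
                             "x_nm": 0.0, "y_nm": 0.0})
        counts = tracking.detections_per_frame(locs)
        assert (counts == 4).all()
        assert counts.sum() == len(locs)

    def test_detections_decay_shape_recovered(self):
        # detection probability decaying to a plateau: fitted decay constant
        # should match the generator within a third
        rng = np.random.default_rng(9)
        frames = np.arange(200)
        lam = 20 * np.exp(-frames / 30.0) + 5
        counts = rng.poisson(lam)
        locs = pd.DataFrame({"frame": np.repeat(frames, counts), "x_nm": 0.0})
        got = tracking.detections_per_frame(locs)
        from scipy.optimize import curve_fit
        popt, _ = curve_fit(lambda f, a, k, c: a * np.exp(-f / k) + c,
                            got.index.to_numpy(), got.to_numpy(),
                            p0=(10.0, 50.0, 1.0))
        assert popt[1] == pytest.approx(30.0, rel=0.33)


class TestArrivalCdf:
    def test_step_cdf_for_simultaneous_arrivals(self):
        sites = pd.DataFrame({"x_nm": np.zeros(10), "y_nm": 0.0, "z_nm": 0.0,
                              "start_frame": 1})
        curves = tracking.arrival_cdf(sites)
        assert len(curves) == 1
        c = curves[0]
        assert (c["start_frame"] == 1).all()
        assert c["cdf"].iloc[-1] == 1.0

    def test_uniform_arrivals_linear_cdf(self):
        rng = np.random.default_rng(10)
        sites = pd.DataFrame({"x_nm": rng.normal(0, 50, 400), "y_nm": 0.0,
                              "z_nm": 0.0,
                              "start_frame": rng.integers(0, 1000, 400)})
        c = tracking.arrival_cdf(sites)[0]
        stat = kstest(c["start_frame"] / 1000.0, "uniform")
        assert stat.pvalue > 0.01

    def test_canopy_separates_distant_clusters(self):
        pts = np.vstack([np.zeros((5, 3)), np.full((5, 3), 3000.0)])
        sites = pd.DataFrame(pts, columns=["x_nm", "y_nm", "z_nm"])
        sites["start_frame"] = np.arange(10)
        curves = tracking.arrival_cdf(sites, canopy_radius_nm=400.0)
        assert len(curves) == 2
        assert all(len(c) == 5 for c in curves.values())
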