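"""Normalisation, sleep onset, sleep distance and trajectory kinematics."""

import numpy as np
import pytest

from somnifold.features.registry import FeatureTimeseries
from somnifold.io import Hypnogram
from somnifold.statespace import (bootstrap_group_trace, causal_median,
                                  compute_normalization, kinematics,
                                  latency_excluded, mean_sleep_score_post_onset,
                                  onset_centroid, sleep_distance,
                                  sleep_onset_time, zscore)


def make_ft(values, t=None):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.shape[1]) * 3.0 if t is None else t
    return FeatureTimeseries(values, [f"f{i}" for i in range(values.shape[0])], t)


class TestOnset:
    def test_first_two_consecutive_n2(self):
        assert sleep_onset_time(Hypnogram(["W", "W", "N1", "N2", "N2"])) == 90.0

    def test_isolated_n2_ignored(self):
        assert sleep_onset_time(Hypnogram(["W", "N2", "W", "N2", "N2"])) == 90.0

    def test_no_onset_raises(self):
        with pytest.raises(ValueError, match="onset"):
            sleep_onset_time(Hypnogram(["W", "N1", "N2", "W"]))

    def test_latency_window(self):
        assert latency_excluded(2 * 60.0)       # < 3 min
        assert latency_excluded(95 * 60.0)      # > 90 min
        assert not latency_excluded(30 * 60.0)

    def test_mean_sleep_score(self):
        # 10-min window = 20 epochs: ten N2 (score 2) + ten N1 (score 1)
        hyp = Hypnogram(["W"] * 2 + ["N2"] * 10 + ["N1"] * 10)
        assert mean_sleep_score_post_onset(hyp, 60.0, 600.0) == 1.5
        assert mean_sleep_score_post_onset(
            Hypnogram(["N2"] * 22), 0.0, 600.0) == 2.0


class TestZScore:
    def test_own_stats_give_unit_moments(self, rng):
        ft = make_ft(rng.normal(5, 3, (4, 300)))
        z = zscore(ft)
        np.testing.assert_allclose(np.nanmean(z.values, axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(np.nanstd(z.values, axis=1), 1, atol=1e-12)

    def test_constant_feature_named_in_error(self, rng):
        vals = rng.normal(0, 1, (3, 50))
        vals[1] = 2.0
        ft = make_ft(vals)
        with pytest.raises(ValueError, match="f1"):
            zscore(ft)

    def test_foreign_stats_not_recentered(self, rng):
        train = make_ft(rng.normal(5, 2, (3, 200)))
        test = make_ft(rng.normal(8, 2, (3, 200)))
        stats = compute_normalization(train)
        z = zscore(test, stats)
        assert np.abs(np.nanmean(z.values)) > 0.5


class TestCentroid:
    def test_constant_post_onset_features(self, rng):
        t = np.arange(400) * 3.0
        vals = rng.normal(0, 1, (3, 400))
        post = t >= 600.0
        vals[:, post] = np.array([1.0, 2.0, 3.0])[:, None]
        ft = make_ft(vals, t)
        np.testing.assert_allclose(onset_centroid(ft, 600.0), [1, 2, 3])

    def test_median_robust_to_outlier_epoch(self, rng):
        t = np.arange(400) * 3.0
        vals = np.ones((2, 400))
        vals[:, 250] = 1e6
        ft = make_ft(vals, t)
        np.testing.assert_allclose(onset_centroid(ft, 600.0), [1, 1])

    def test_window_covers_199_epochs(self):
        t = np.arange(400) * 3.0
        ft = make_ft(np.ones((1, 400)), t)
        sel = (t >= 600.0) & (t < 1200.0)
        assert sel.sum() == 200  # 10 min at the 3-s hop (inclusive start)
        with pytest.raises(ValueError):
            onset_centroid(make_ft(np.ones((1, 100))), 600.0)


class TestSleepDistance:
    def test_norm_recovers_generator_exactly(self, rng):
        s_true = np.abs(np.sin(np.arange(500) / 40)) * 5 + 0.5
        dirs = rng.standard_normal(8)
        dirs /= np.linalg.norm(dirs)
        ft = make_ft(dirs[:, None] * s_true[None, :])
        sd = sleep_distance(ft, np.zeros(8))
        np.testing.assert_allclose(sd.s_raw, s_true, atol=1e-9)
        assert sd.gap == pytest.approx(s_true.min())
        assert np.all(sd.s >= 0)

    def test_norm_homogeneity(self, rng):
        vals = rng.standard_normal((5, 100))
        a = sleep_distance(make_ft(vals), np.zeros(5))
        b = sleep_distance(make_ft(2 * vals), np.zeros(5))
        np.testing.assert_allclose(b.s_raw, 2 * a.s_raw)

    def test_invariant_to_feature_permutation_and_constant_padding(self, rng):
        vals = rng.standard_normal((5, 80))
        c = rng.standard_normal(5)
        base = sleep_distance(make_ft(vals), c)
        perm = rng.permutation(5)
        p = sleep_distance(make_ft(vals[perm]), c[perm])
        np.testing.assert_allclose(p.s_raw, base.s_raw)
        # a feature constant at its centroid value adds nothing except the
        # sqrt(M/M) rescale, which is exact here (no NaNs)
        vals6 = np.vstack([vals, np.full(80, 7.0)])
        c6 = np.r_[c, 7.0]
        s6 = sleep_distance(make_ft(vals6), c6)
        np.testing.assert_allclose(s6.s_raw, base.s_raw * np.sqrt(6 / 5)
                                   / np.sqrt(6 / 5))

    def test_nan_features_rescaled(self):
        vals = np.ones((4, 10))
        vals[0, 5] = np.nan
        sd = sleep_distance(make_ft(vals), np.zeros(4))
        # epoch 5: 3 valid ones, rescaled by sqrt(4/3)
        assert sd.s_raw[5] == pytest.approx(np.sqrt(3 * 4 / 3))
        assert sd.s_raw[0] == pytest.approx(2.0)

    def test_all_nan_epoch_gives_nan(self):
        vals = np.ones((2, 5))
        vals[:, 2] = np.nan
        sd = sleep_distance(make_ft(vals), np.zeros(2))
        assert np.isnan(sd.s[2])


class TestKinematics:
    def test_projection_bound_everywhere(self, rng):
        ft = make_ft(rng.standard_normal((6, 300)))
        kin = kinematics(ft, rng.standard_normal(6))
        assert np.all(np.abs(kin.sleep_velocity) <= kin.state_speed + 1e-12)

    def test_radial_motion_saturates_bound(self):
        t = np.arange(50) * 3.0
        s = np.linspace(10, 1, 50)
        d = np.array([0.6, 0.8])
        ft = make_ft(d[:, None] * s[None, :], t)
        kin = kinematics(ft, np.zeros(2))
        np.testing.assert_allclose(np.abs(kin.sleep_velocity),
                                   kin.state_speed, atol=1e-12)

    def test_circular_motion_has_zero_sleep_velocity(self):
        th = np.arange(200) / 30
        ft = make_ft(np.vstack([np.cos(th), np.sin(th)]))
        kin = kinematics(ft, np.zeros(2))
        assert np.max(np.abs(kin.sleep_velocity)) < 1e-12
        assert kin.state_speed.min() > 0
        assert np.all(kin.energy == kin.sleep_velocity**2)


class TestCausalMedian:
    def test_constant_unchanged(self):
        x = np.full(50, 3.0)
        np.testing.assert_array_equal(causal_median(x), x)

    def test_single_spike_removed(self):
        x = np.zeros(40)
        x[20] = 100.0
        out = causal_median(x, window=5)
        assert out[20] == 0.0

    def test_strict_causality_under_future_edits(self, rng):
        x = rng.standard_normal(200)
        out1 = causal_median(x, 20)
        x2 = x.copy()
        x2[120:] = 99.0
        out2 = causal_median(x2, 20)
        np.testing.assert_array_equal(out1[:120], out2[:120])


class TestGroupTrace:
    def _series(self, t, v):
        return type("S", (), {"t": t, "s": v})()

    def test_identical_series_reproduce_common_trace(self, rng):
        t = np.arange(-100, 50) * 3.0
        v = np.linspace(5, 1, len(t))
        series = [self._series(t, v)] * 10
        grid, trace, sig, p = bootstrap_group_trace(series, n_per_timestamp=10,
                                                    seed=0)
        inner = (grid > t[0] + 60) & (grid < t[-1] - 60)
        np.testing.assert_allclose(trace[inner], np.interp(grid, t, v)[inner],
                                   atol=0.05)

    def test_cutoff_at_required_count(self, rng):
        long_t = np.arange(-200, 50) * 3.0
        short_t = np.arange(-50, 50) * 3.0
        series = [self._series(long_t, np.ones(len(long_t)))] * 4 \
            + [self._series(short_t, np.ones(len(short_t)))] * 8
        grid, *_ = bootstrap_group_trace(series, n_per_timestamp=10, seed=0)
        assert grid[0] == short_t[0]  # only 4 series reach earlier times

    def test_step_change_detected_after_baseline(self, rng):
        t = np.arange(-300, 100) * 3.0
        series = []
        for _ in range(40):
            v = np.where(t < 0, 5.0, 2.0) + rng.normal(0, 0.4, len(t))
            series.append(self._series(t, v))
        grid, trace, sig, p = bootstrap_group_trace(series,
                                                    n_per_timestamp=40,
                                                    seed=1, tail="left")
        assert sig[grid > 60].mean() > 0.9
        assert not sig[(grid > grid[0] + 650) & (grid < -200 * 3)].any()
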