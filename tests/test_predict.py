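"""Cross-night centroid consistency and streamed prediction."""

import numpy as np
import pytest

from somnifold.predict import (PredictionResult, SleepDistancePredictor,
                               centroid_consistency, evaluate)
from somnifold.statespace import (SleepDistanceSeries, compute_normalization,
                                  onset_centroid, sleep_distance,
                                  sleep_onset_time, zscore)


@pytest.fixture(scope="module")
def trained(cohort, cohort_features):
    sid, nid, rec, hyp = cohort[0]
    model = SleepDistancePredictor(feature_set=47).fit(
        [(rec, hyp)], features=[cohort_features[(sid, nid)]])
    return model


class TestTraining:
    def test_self_prediction_matches_posthoc_trace(self, cohort,
                                                   cohort_features, trained):
        sid, nid, rec, hyp = cohort[0]
        ft = cohort_features[(sid, nid)]
        res = trained.predict(rec, hyp, features=ft)
        onset = sleep_onset_time(hyp)
        ftz = zscore(ft, compute_normalization(ft))
        sd = sleep_distance(ftz, onset_centroid(ftz, onset),
                            onset_time=onset)
        # identical normalisation/centroid/gap: streamed trace equals the
        # causal-median-filtered post-hoc trace
        from somnifold.statespace import causal_median
        np.testing.assert_allclose(res.s_hat, causal_median(sd.s, 20),
                                   atol=1e-9)
        cos, _ = evaluate(res, sd)
        assert cos > 0.97

    def test_two_identical_training_nights_equal_one(self, cohort,
                                                     cohort_features):
        sid, nid, rec, hyp = cohort[0]
        ft = cohort_features[(sid, nid)]
        one = SleepDistancePredictor(feature_set=47).fit(
            [(rec, hyp)], features=[ft])
        two = SleepDistancePredictor(feature_set=47).fit(
            [(rec, hyp), (rec, hyp)], features=[ft, ft])
        np.testing.assert_allclose(one.centroid_, two.centroid_)
        assert one.gap_ == pytest.approx(two.gap_)

    def test_cross_night_similarity(self, cohort, cohort_features, trained):
        sid, nid, rec2, hyp2 = cohort[1]  # same subject, night 2
        assert sid == cohort[0][0]
        ft2 = cohort_features[(sid, nid)]
        res = trained.predict(rec2, hyp2, features=ft2)
        onset = sleep_onset_time(hyp2)
        ftz = zscore(ft2, compute_normalization(ft2))
        sd = sleep_distance(ftz, onset_centroid(ftz, onset), onset_time=onset)
        cos, _ = evaluate(res, sd)
        assert cos >= 0.9


class TestStreamingCausality:
    def test_future_edits_never_change_past_outputs(self, trained, rng):
        m = len(trained.centroid_)
        stream = rng.normal(0, 1, (120, m)) * trained.stats_.sd \
            + trained.stats_.mean
        out = trained.predict_stream(stream)
        for cut in rng.integers(10, 110, size=5):
            edited = stream.copy()
            edited[cut:] += 50.0
            out2 = trained.predict_stream(edited)
            np.testing.assert_array_equal(out[:cut], out2[:cut])

    def test_truncation_invariance(self, trained, rng):
        m = len(trained.centroid_)
        stream = rng.normal(0, 1, (80, m))
        full = trained.predict_stream(stream)
        half = trained.predict_stream(stream[:40])
        np.testing.assert_array_equal(full[:40], half)

    def test_constant_stream_at_centroid_floors_at_zero(self, trained):
        vec = trained.stats_.mean + trained.stats_.sd * trained.centroid_
        out = trained.predict_stream(np.tile(vec, (30, 1)))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_missing_features_emit_nan_and_filter_skips(self, trained):
        m = len(trained.centroid_)
        stream = np.zeros((10, m))
        stream[4] = np.nan
        out = trained.predict_stream(stream)
        assert np.isnan(out).sum() == 0  # filter skips the NaN sample
        raw_nan = trained.predict_stream(np.full((1, m), np.nan))
        assert np.isnan(raw_nan[0])


class TestTippingRules:
    def _result(self, s_hat, dt=3.0, t0=-600.0):
        t = t0 + np.arange(len(s_hat)) * dt
        return PredictionResult(t=t, s_hat=np.asarray(s_hat, float))

    def _model(self, x_star):
        m = SleepDistancePredictor()
        m.critical_distance_ = x_star
        m.tipping_enabled_ = True
        return m

    def test_single_monotone_crossing(self):
        s = np.linspace(5, 0, 100)
        res = self._model(2.0).predict_tipping(self._result(s), 0.0)
        assert len(res.valid_crossings) == 1
        assert res.predicted_tipping == res.valid_crossings[0]
        assert res.erroneous_early == []
        assert not res.invalid

    def test_short_dip_discarded(self):
        # 30-s dip below threshold, recovery, then the final descent
        s = np.r_[np.full(50, 5.0), np.full(10, 1.0), np.full(50, 5.0),
                  np.linspace(5, 0, 60)]
        res = self._model(2.0).predict_tipping(self._result(s), 0.0)
        assert len(res.valid_crossings) == 1  # dip < 1 min not valid
        assert res.erroneous_early == []

    def test_two_sustained_dips_first_is_erroneous_early(self):
        s = np.r_[np.full(40, 5.0), np.full(30, 1.0), np.full(40, 5.0),
                  np.linspace(5, 0, 60)]
        res = self._model(2.0).predict_tipping(self._result(s), 0.0)
        assert len(res.valid_crossings) == 2
        assert res.predicted_tipping == res.valid_crossings[1]
        assert res.erroneous_early == [res.valid_crossings[0]]

    def test_tipping_after_onset_is_invalid(self):
        s = np.r_[np.full(250, 5.0), np.linspace(5, 0, 60)]
        res = self._model(2.0).predict_tipping(self._result(s), 0.0)
        assert res.predicted_tipping > 0
        assert res.invalid

    def test_no_crossing_flagged(self):
        res = self._model(2.0).predict_tipping(
            self._result(np.full(100, 5.0)), 0.0)
        assert res.predicted_tipping is None

    def test_disabled_tipping_raises(self):
        m = SleepDistancePredictor()
        m.tipping_enabled_ = False
        with pytest.raises(RuntimeError):
            m.predict_tipping(self._result(np.zeros(10)), 0.0)


class TestCentroidConsistency:
    def test_separated_subjects_significant(self, rng):
        cents = np.r_[rng.normal(0, 0.1, (6, 5)), rng.normal(3, 0.1, (6, 5))]
        labels = ["a"] * 6 + ["b"] * 6
        score, p = centroid_consistency(cents, labels, n_surrogates=200,
                                        seed=0)
        assert score > 0.8 and p < 0.05

    def test_geometry_independent_labels_null(self, rng):
        pvals = []
        for rep in range(10):
            cents = rng.normal(0, 1, (12, 5))
            labels = ["a", "b", "c"] * 4
            pvals.append(centroid_consistency(cents, labels,
                                              n_surrogates=100,
                                              seed=rep)[1])
        assert np.mean(np.array(pvals) < 0.05) <= 0.2

    def test_identical_centroids_score_near_zero(self, rng):
        cents = np.ones((8, 4)) + rng.normal(0, 1e-9, (8, 4))
        score, p = centroid_consistency(cents, ["a"] * 4 + ["b"] * 4,
                                        n_surrogates=50, seed=1)
        assert abs(score) < 0.3

    def test_single_night_subject_excluded(self, rng):
        cents = rng.normal(0, 1, (5, 3))
        labels = ["a", "a", "b", "b", "c"]
        with pytest.warns(UserWarning, match="single-night"):
            centroid_consistency(cents, labels, n_surrogates=20, seed=0)


class TestEvaluate:
    def _series(self, t, s):
        return SleepDistanceSeries(t=t, s=s, s_raw=s, gap=0.0)

    def test_identical_series(self):
        t = np.arange(-50, 10) * 3.0
        s = np.abs(np.sin(t / 40)) + 1
        pred = PredictionResult(t=t, s_hat=s, predicted_tipping=-120.0)
        cos, err = evaluate(pred, self._series(t, s), posthoc_tipping_min=-2.0)
        assert cos == pytest.approx(1.0)
        assert err == pytest.approx(0.0)

    def test_scale_invariance_of_cosine(self):
        t = np.arange(40) * 3.0
        s = np.linspace(5, 1, 40)
        pred = PredictionResult(t=t, s_hat=2 * s)
        cos, _ = evaluate(pred, self._series(t, s))
        assert cos == pytest.approx(1.0)

    def test_signed_tipping_error(self):
        t = np.arange(40) * 3.0
        s = np.ones(40)
        pred = PredictionResult(t=t, s_hat=s, predicted_tipping=0.0)
        _, err = evaluate(pred, self._series(t, s), posthoc_tipping_min=-2.0)
        assert err == pytest.approx(2.0)

    def test_disjoint_grids_rejected(self):
        pred = PredictionResult(t=np.arange(10) * 3.0, s_hat=np.ones(10))
        far = self._series(np.arange(100, 110) * 3.0, np.ones(10))
        with pytest.raises(ValueError):
            evaluate(pred, far)
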