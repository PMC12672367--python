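"""Pseudo-real-time prediction of sleep distance and tipping-point crossing.

A :class:`SleepDistancePredictor` is trained on one or more nights of a
subject: it stores the sleep-onset centroid (per-feature median over the
first 10 min of sleep), the training night's normalisation statistics and
gap correction, and the critical sleep distance x* at which the fitted
fold model tips.  On a test night each incoming 6-s epoch is featurised,
z-scored with the *training* statistics, its Euclidean distance to the
trained centroid computed, gap-corrected, and causally median-filtered
(window 20) — using only past data.  Tipping is predicted online as the
last downward crossing of x* that stays below for at least 1 min and is
never followed by an upward re-cross.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import silhouette_score

from .bifurcation import BifurcationModel
from .features.registry import FeatureExtractor, FeatureTimeseries
from .fpca import cosine_similarity
from .io import EEGRecording, Hypnogram
from .statespace import (NormalizationStats, SleepDistanceSeries,
                         causal_median, compute_normalization, onset_centroid,
                         sleep_distance, sleep_onset_time, zscore)

__all__ = ["SleepDistancePredictor", "PredictionResult",
           "centroid_consistency", "train", "evaluate"]

SUSTAIN_S = 60.0  # a crossing must stay below x* for >= 1 min to be valid


@dataclass
class PredictionResult:
    t: np.ndarray                 # seconds relative to sleep onset
    s_hat: np.ndarray             # streamed sleep-distance prediction
    crossings: list[float] = field(default_factory=list)
    valid_crossings: list[float] = field(default_factory=list)
    erroneous_early: list[float] = field(default_factory=list)
    predicted_tipping: float | None = None
    invalid: bool = False         # tipping predicted after sleep onset
    cosine_similarity: float | None = None
    tipping_error_min: float | None = None


class SleepDistancePredictor(BaseEstimator):
    """Train on prior nights; stream s(t) and tipping predictions.

    Parameters
    ----------
    feature_set : 47 (default, the streaming feature base) or 50.
    smoothing_window : causal median window (samples at the 3-s hop).
    fit_window_min : minutes of pre-onset trace used for the training-night
        bifurcation fit (30, or less for shorter latencies).

    Attributes (after fit): ``centroid_``, ``stats_``, ``gap_``,
    ``bifurcation_``, ``critical_distance_``, ``tipping_enabled_``.
    """

    def __init__(self, feature_set: int = 47, cfg=None, region=None,
                 smoothing_window: int = 20, fit_window_min: float = 30.0):
        self.feature_set = feature_set
        self.cfg = cfg
        self.region = region
        self.smoothing_window = smoothing_window
        self.fit_window_min = fit_window_min

    # -- training ----------------------------------------------------------

    def _night_features(self, rec: EEGRecording) -> FeatureTimeseries:
        ext = FeatureExtractor(feature_set=self.feature_set, cfg=self.cfg,
                               region=self.region)
        return ext.transform(rec)

    def _night_quantities(self, rec, hyp, features=None):
        ft = self._night_features(rec) if features is None else features
        onset = sleep_onset_time(hyp)
        stats = compute_normalization(ft)
        ftz = zscore(ft, stats)
        centroid = onset_centroid(ftz, onset)
        sd = sleep_distance(ftz, centroid, onset_time=onset)
        return ft, onset, stats, centroid, sd

    def fit(self, nights, features=None):
        """Train from ``[(recording, hypnogram), ...]`` (or one tuple).

        ``features`` optionally supplies precomputed
        :class:`FeatureTimeseries` per night (same order) to avoid
        re-extraction.  Multi-night training pools centroids by median and
        normalisation statistics over all training epochs; the critical
        distance is the median over the nights whose fold fit succeeded.
        """
        if isinstance(nights, tuple) and isinstance(nights[0], EEGRecording):
            nights = [nights]
        feats = features if features is not None else [None] * len(nights)
        cents, gaps, stats_all, xstars, fits = [], [], [], [], []
        for (rec, hyp), ft in zip(nights, feats):
            ft, onset, stats, centroid, sd = self._night_quantities(
                rec, hyp, ft)
            cents.append(centroid)
            gaps.append(sd.gap)
            stats_all.append(ft)
            model = self._fit_training_trace(sd)
            fits.append(model)
            if model is not None and not model.failed_:
                xstars.append(model.critical_distance_)
        self.stats_ = compute_normalization(stats_all) if len(stats_all) > 1 \
            else compute_normalization(stats_all[0])
        self.centroid_ = np.median(np.stack(cents), axis=0)
        self.gap_ = float(np.median(gaps))
        self.bifurcation_ = fits[0] if len(fits) == 1 else fits
        if xstars:
            self.critical_distance_ = float(np.median(xstars))
            self.tipping_enabled_ = True
        else:
            warnings.warn("training-night bifurcation fit failed; tipping "
                          "prediction disabled")
            self.critical_distance_ = np.nan
            self.tipping_enabled_ = False
        return self

    def _fit_training_trace(self, sd: SleepDistanceSeries):
        pre = sd.t <= 0
        t0 = max(sd.t[pre][0], -self.fit_window_min * 60.0)
        win = (sd.t >= t0) & (sd.t <= 0)
        if win.sum() < 30:
            return None
        smooth = causal_median(sd.s[win], self.smoothing_window)
        try:
            return BifurcationModel().fit(sd.t[win] / 60.0, smooth)
        except (ValueError, RuntimeError):
            return None

    # -- streaming ---------------------------------------------------------

    def predict_stream(self, feature_vectors, times=None) -> np.ndarray:
        """Streamed s-hat from per-epoch feature vectors (time order).

        Each update uses only past data: z-score with training statistics,
        distance to the trained centroid with the training gap correction,
        then a causal median.  Missing (NaN) features are skipped inside
        the norm; an all-NaN epoch emits NaN and is skipped by the filter.
        """
        fv = np.asarray(feature_vectors, dtype=float)
        if fv.ndim == 1:
            fv = fv[None]
        raw = np.empty(len(fv))
        buf: list[float] = []
        out = np.empty(len(fv))
        m = len(self.centroid_)
        for i, vec in enumerate(fv):
            z = (vec - self.stats_.mean) / self.stats_.sd
            diff = z - self.centroid_
            good = np.isfinite(diff)
            if not good.any():
                raw[i] = np.nan
            else:
                raw[i] = np.sqrt(np.sum(diff[good] ** 2) * m / good.sum())
            val = max(raw[i] - self.gap_, 0.0) if np.isfinite(raw[i]) else np.nan
            buf.append(val)
            win = [v for v in buf[-self.smoothing_window:] if np.isfinite(v)]
            out[i] = np.median(win) if win else np.nan
        return out

    def predict(self, rec: EEGRecording, hyp: Hypnogram | None = None,
                features: FeatureTimeseries | None = None) -> PredictionResult:
        """Convenience batch predictor for a full test night."""
        ft = self._night_features(rec) if features is None else features
        s_hat = self.predict_stream(ft.values.T)
        onset = sleep_onset_time(hyp) if hyp is not None else 0.0
        return PredictionResult(t=ft.epoch_times - onset, s_hat=s_hat)

    # -- tipping -----------------------------------------------------------

    def predict_tipping(self, result: PredictionResult,
                        onset_time: float = 0.0) -> PredictionResult:
        """Mark x* crossings on a streamed trace and pick the prediction.

        Valid crossings stay below x* for at least 1 min; the predicted
        tipping point is the last valid crossing with no later upward
        re-cross; earlier valid crossings are erroneous early predictions;
        the prediction is invalid if it falls after sleep onset.
        """
        if not self.tipping_enabled_:
            raise RuntimeError("tipping prediction disabled (training fit failed)")
        x_star = self.critical_distance_
        t, s = result.t, result.s_hat
        below = s < x_star
        cross_idx = [i for i in range(1, len(s))
                     if below[i] and not below[i - 1]
                     and np.isfinite(s[i]) and np.isfinite(s[i - 1])]
        result.crossings = [float(t[i]) for i in cross_idx]
        valid = []
        for i in cross_idx:
            t_end = t[i] + SUSTAIN_S
            seg = below[i:][t[i:] <= t_end]
            if len(seg) and seg.all() and t[-1] >= t_end:
                valid.append(i)
        result.valid_crossings = [float(t[i]) for i in valid]
        if not valid:
            result.predicted_tipping = None
            return result
        final = None
        for i in valid:
            if below[i:].all():  # never re-crosses upward
                final = i
                break
        if final is None:
            final = valid[-1]
            result.erroneous_early = [float(t[i]) for i in valid[:-1]]
        else:
            result.erroneous_early = [float(t[i]) for i in valid if i < final]
        result.predicted_tipping = float(t[final])
        result.invalid = bool(t[final] > onset_time)
        return result


# ---------------------------------------------------------------------------
# Cross-night centroid consistency
# ---------------------------------------------------------------------------

def centroid_consistency(centroids: np.ndarray, subject_labels,
                         n_surrogates: int = 1000, seed: int = 0):
    """Silhouette test of sleep-onset-centroid clustering by subject.

    ``centroids``: (n_nights, n_features); surrogates shuffle the subject
    labels across nights; p = fraction of surrogates with a higher
    silhouette than the original labelling (p < 0.05 = consistent).
    Subjects contributing a single night are excluded with a warning.
    """
    centroids = np.asarray(centroids, dtype=float)
    labels = np.asarray(subject_labels)
    uniq, counts = np.unique(labels, return_counts=True)
    singletons = uniq[counts < 2]
    if len(singletons):
        warnings.warn(f"excluding single-night subject(s): {list(singletons)}")
        keep = ~np.isin(labels, singletons)
        centroids, labels = centroids[keep], labels[keep]
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 subjects with >= 2 nights")
    score = silhouette_score(centroids, labels)
    rng = np.random.default_rng(seed)
    higher = 0
    for _ in range(n_surrogates):
        perm = rng.permutation(labels)
        while len(np.unique(perm)) < 2:
            perm = rng.permutation(labels)
        if silhouette_score(centroids, perm) > score:
            higher += 1
    return float(score), higher / n_surrogates


def train(nights, **kwargs) -> SleepDistancePredictor:
    """Fit a :class:`SleepDistancePredictor` on training night(s)."""
    return SleepDistancePredictor(**kwargs).fit(nights)


def evaluate(prediction: PredictionResult, posthoc: SleepDistanceSeries,
             posthoc_tipping_min: float | None = None):
    """Cosine similarity of the streamed trace against the post-hoc s(t)
    (on their overlapping finite samples) and the signed tipping error in
    minutes."""
    t_pred = np.round(prediction.t / 3.0).astype(int)
    t_post = np.round(np.asarray(posthoc.t) / 3.0).astype(int)
    common, ia, ib = np.intersect1d(t_pred, t_post, return_indices=True)
    if len(common) == 0:
        raise ValueError("no overlapping timestamps")
    a = prediction.s_hat[ia]
    b = np.asarray(posthoc.s)[ib]
    ok = np.isfinite(a) & np.isfinite(b)
    if not ok.any():
        raise ValueError("no overlapping finite samples")
    cos = cosine_similarity(a[ok], b[ok])
    prediction.cosine_similarity = cos
    err = None
    if posthoc_tipping_min is not None and prediction.predicted_tipping is not None:
        err = prediction.predicted_tipping / 60.0 - posthoc_tipping_min
        prediction.tipping_error_min = err
    return cos, err
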