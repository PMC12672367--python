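"""Feature-space trajectory analysis: normalisation, sleep onset, the
sleep distance s(t) and its kinematics, and group-level traces.

Sleep onset is the start of the first run of two consecutive N2 epochs
(the first continuous minute of N2).  Features are z-scored (per recording
or with cohort-pooled statistics), referenced to the sleep-onset centroid
(per-feature median over the first 10 min after onset, 199 epochs at the
3-s hop), and the sleep distance is the Euclidean norm of the referenced
feature vector, gap-corrected by subtracting its minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .features.registry import FeatureTimeseries
from .io import Hypnogram, EPOCH_LEN_S

__all__ = [
    "NormalizationStats", "SleepDistanceSeries", "TrajectoryKinematics",
    "sleep_onset_time", "latency_excluded", "compute_normalization",
    "zscore", "onset_centroid", "sleep_distance", "kinematics",
    "causal_median", "bootstrap_group_trace", "mean_sleep_score_post_onset",
]

LATENCY_MIN_S = 3 * 60.0
LATENCY_MAX_S = 90 * 60.0
ONSET_WINDOW_S = 600.0  # 10 min defining the sleep-onset centroid


@dataclass
class NormalizationStats:
    """Per-feature mean and s.d.; scope is 'recording' or 'cohort'."""

    mean: np.ndarray
    sd: np.ndarray
    feature_names: list[str]
    scope: str = "recording"

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        bad = np.flatnonzero(~(self.sd > 0))
        if len(bad):
            names = [self.feature_names[i] for i in bad]
            raise ValueError(f"zero/invalid s.d. for feature(s): {names}")


@dataclass
class SleepDistanceSeries:
    """s(t) relative to the sleep-onset centroid; onset at t = 0."""

    t: np.ndarray        # seconds relative to sleep onset
    s: np.ndarray        # gap-corrected distance (s.d. units), >= 0
    s_raw: np.ndarray    # before gap correction
    gap: float           # subtracted minimum distance

    @property
    def t_min(self) -> np.ndarray:
        return self.t / 60.0


@dataclass
class TrajectoryKinematics:
    """State velocity, sleep velocity and kinetic-energy proxy."""

    t: np.ndarray
    state_speed: np.ndarray     # |dx/dt| in the M-dim feature space
    sleep_velocity: np.ndarray  # ds/dt, the radial component
    energy: np.ndarray          # E_s = (ds/dt)^2


def sleep_onset_time(hypnogram: Hypnogram) -> float:
    """Start time (s from recording start) of the first run of >= 2
    consecutive N2 epochs."""
    st = hypnogram.stages
    for i in range(len(st) - 1):
        if st[i] == "N2" and st[i + 1] == "N2":
            return i * hypnogram.epoch_len
    raise ValueError("no sleep onset: hypnogram has no two consecutive N2 epochs")


def latency_excluded(onset_s: float, bedtime_s: float = 0.0) -> bool:
    """True if the sleep latency falls outside the [3, 90]-min window."""
    latency = onset_s - bedtime_s
    return latency < LATENCY_MIN_S or latency > LATENCY_MAX_S


def mean_sleep_score_post_onset(hypnogram: Hypnogram, onset_s: float,
                                window_s: float = ONSET_WINDOW_S) -> float:
    """Mean numeric sleep score (W=0, N1=1, N2=2, N3=3) over the first
    10 min after onset; < 1.5 marks an unstable onset excluded from
    individual-level fitting."""
    scores = hypnogram.sleep_scores()
    i0 = int(onset_s // hypnogram.epoch_len)
    i1 = int((onset_s + window_s) // hypnogram.epoch_len)
    return float(np.mean(scores[i0:min(i1, len(scores))]))


def compute_normalization(features: FeatureTimeseries | list,
                          scope: str = "recording") -> NormalizationStats:
    """Mean/s.d. per feature over all epochs of one recording, or pooled
    across a cohort of feature matrices."""
    if isinstance(features, FeatureTimeseries):
        mats = [features.values]
        names = features.feature_names
    else:
        mats = [f.values for f in features]
        names = features[0].feature_names
        scope = "cohort"
    pooled = np.concatenate(mats, axis=1)
    return NormalizationStats(np.nanmean(pooled, axis=1),
                              np.nanstd(pooled, axis=1), list(names), scope)


def zscore(features: FeatureTimeseries,
           stats: NormalizationStats | None = None) -> FeatureTimeseries:
    """Z-score each feature; by default to its own mean/s.d. over the trace."""
    if stats is None:
        stats = compute_normalization(features)
    if stats.feature_names != features.feature_names:
        raise ValueError("normalization statistics do not match the features")
    vals = (features.values - stats.mean[:, None]) / stats.sd[:, None]
    return FeatureTimeseries(vals, list(features.feature_names),
                             features.epoch_times, features.channel_set)


def onset_centroid(features: FeatureTimeseries, onset_time: float,
                   window_s: float = ONSET_WINDOW_S) -> np.ndarray:
    """Per-feature median over the first 10 min after sleep onset."""
    sel = (features.epoch_times >= onset_time) \
        & (features.epoch_times < onset_time + window_s)
    if features.epoch_times[-1] < onset_time + window_s - 3.0:
        raise ValueError("fewer than 10 min of epochs after sleep onset")
    return np.nanmedian(features.values[:, sel], axis=1)


def sleep_distance(features: FeatureTimeseries, centroid: np.ndarray,
                   onset_time: float = 0.0,
                   gap: float | None = None) -> SleepDistanceSeries:
    """Euclidean distance of each epoch's feature vector to the centroid.

    NaN features are skipped with a sqrt(M / M_valid) rescale so the
    distance scale stays comparable across epochs; an all-NaN epoch yields
    NaN.  ``gap`` defaults to the trace minimum ("gap correction"); pass a
    training-night gap for streamed prediction.  Time is re-zeroed at
    ``onset_time``.
    """
    centroid = np.asarray(centroid, dtype=float)
    if centroid.shape[0] != features.n_features:
        raise ValueError("centroid dimension does not match the features")
    diff = features.values - centroid[:, None]
    valid = np.isfinite(diff)
    m_valid = valid.sum(axis=0)
    sq = np.where(valid, diff**2, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s_raw = np.sqrt(sq * features.n_features / m_valid)
    s_raw[m_valid == 0] = np.nan
    if gap is None:
        gap = float(np.nanmin(s_raw))
    s = np.maximum(s_raw - gap, 0.0)
    return SleepDistanceSeries(features.epoch_times - onset_time, s, s_raw,
                               float(gap))


def kinematics(features: FeatureTimeseries, centroid: np.ndarray,
               onset_time: float = 0.0) -> TrajectoryKinematics:
    """Finite-difference state speed and sleep velocity at the 3-s hop.

    The sleep velocity is the radial component of the state velocity,
    which equals the time derivative of the distance; |ds/dt| <= |dx/dt|
    always (projection bound).
    """
    if features.n_epochs < 2:
        raise ValueError("need at least 2 epochs")
    x = features.values - np.asarray(centroid, dtype=float)[:, None]
    t = features.epoch_times
    dt = np.diff(t)
    dx = np.diff(x, axis=1)
    state_speed = np.linalg.norm(dx, axis=0) / dt
    r = np.linalg.norm(x, axis=0)
    sleep_velocity = np.diff(r) / dt
    return TrajectoryKinematics(t[1:] - onset_time, state_speed,
                                sleep_velocity, sleep_velocity**2)


def causal_median(series: np.ndarray, window: int = 20) -> np.ndarray:
    """Causal running-window median: output[t] = median of the last
    min(window, t+1) values up to and including t (no future leakage);
    NaNs are skipped."""
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(series, dtype=float)
    out = np.empty_like(x)
    for i in range(len(x)):
        w = x[max(0, i - window + 1):i + 1]
        w = w[np.isfinite(w)]
        out[i] = np.median(w) if len(w) else np.nan
    return out


def moving_median(series: np.ndarray, window: int = 20) -> np.ndarray:
    """Centred moving median (used for display-level group traces)."""
    x = np.asarray(series, dtype=float)
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        w = x[max(0, i - half):i + window - half]
        w = w[np.isfinite(w)]
        out[i] = np.median(w) if len(w) else np.nan
    return out


def bootstrap_group_trace(series_list: list[SleepDistanceSeries] | list,
                          n_per_timestamp: int = 200, seed: int = 0,
                          smooth_window: int = 20, tail: str = "left",
                          baseline_s: float = 600.0):
    """Bootstrap group-mean trace of onset-aligned series with per-timestamp
    significance against the first-10-min baseline.

    All series must be aligned at onset (t = 0); the trace starts at the
    earliest timestamp with at least ``n_per_timestamp`` finite values.  At
    each timestamp ``n_per_timestamp`` values are drawn at random (with the
    given seed) and averaged; the trace is smoothed with a centred
    20-timestamp moving median; each timestamp's sample is t-tested against
    the pooled first-``baseline_s`` baseline (tail left/right/two-sided),
    Bonferroni-corrected by the number of timestamps.

    Returns ``(t, mean_trace, significant, pvalues)``.
    """
    rng = np.random.default_rng(seed)
    arrs = [(np.asarray(s.t, float), np.asarray(s.s, float))
            if hasattr(s, "t") else (np.asarray(s[0], float),
                                     np.asarray(s[1], float))
            for s in series_list]
    t_min = min(a[0][0] for a in arrs)
    t_max = max(a[0][-1] for a in arrs)
    dt = 3.0
    grid = np.arange(np.round(t_min / dt), np.round(t_max / dt) + 1) * dt
    cols = np.full((len(arrs), len(grid)), np.nan)
    for i, (t, v) in enumerate(arrs):
        idx = np.round((t - grid[0]) / dt).astype(int)
        ok = (idx >= 0) & (idx < len(grid))
        cols[i, idx[ok]] = v[ok]
    counts = np.isfinite(cols).sum(axis=0)
    usable = counts >= n_per_timestamp
    if not usable.any():
        raise ValueError(
            f"no timestamp has {n_per_timestamp} finite values across series")
    first = np.argmax(usable)
    last = len(usable) - np.argmax(usable[::-1])
    grid = grid[first:last]
    cols = cols[:, first:last]

    draws = np.empty((len(grid), n_per_timestamp))
    for j in range(len(grid)):
        vals = cols[:, j]
        vals = vals[np.isfinite(vals)]
        take = rng.choice(len(vals), size=n_per_timestamp,
                          replace=len(vals) < n_per_timestamp)
        draws[j] = vals[take]
    mean_trace = moving_median(draws.mean(axis=1), smooth_window)

    base = draws[grid <= grid[0] + baseline_s].ravel()
    pvals = np.empty(len(grid))
    for j in range(len(grid)):
        res = sp_stats.ttest_ind(draws[j], base, equal_var=False)
        if tail == "two-sided":
            pvals[j] = res.pvalue
        elif tail == "left":
            pvals[j] = res.pvalue / 2 if res.statistic < 0 else 1 - res.pvalue / 2
        elif tail == "right":
            pvals[j] = res.pvalue / 2 if res.statistic > 0 else 1 - res.pvalue / 2
        else:
            raise ValueError("tail must be left, right or two-sided")
    significant = pvals < 0.05 / len(grid)
    return grid, mean_trace, significant, pvals
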