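"""Early-warning signals of critical slowing down on sleep-distance series.

As a dynamical system is driven toward a fold bifurcation its dominant
eigenvalue approaches zero, so fluctuations around the drifting attractor
recover more slowly: lag-1 autocorrelation and variance of the detrended
residuals rise.  ``rolling_ews`` measures both in a trailing 100-sample
(5-min) window after linear detrending within each window;
``trend_test`` asks whether the EWS index increases with time across
subjects using a linear mixed-effects model with a random intercept per
subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EWSSeries", "rolling_ews", "trend_test"]

WINDOW = 100  # samples = 5 min at the 3-s hop


@dataclass
class EWSSeries:
    t: np.ndarray          # time of each (right-aligned) window end
    autocorr: np.ndarray   # lag-1 autocorrelation of detrended residuals
    variance: np.ndarray   # variance of detrended residuals
    sd: np.ndarray         # standard deviation (exposed alongside variance)
    window: int = WINDOW


def _window_ews(w: np.ndarray) -> tuple[float, float]:
    """Lag-1 autocorrelation and variance of the residuals of a linear
    detrend over one window."""
    n = len(w)
    t = np.arange(n, dtype=float)
    tm = t.mean()
    b = np.dot(t - tm, w - w.mean()) / np.dot(t - tm, t - tm)
    res = w - w.mean() - b * (t - tm)
    denom = np.dot(res, res)
    if denom <= 0:
        return np.nan, 0.0
    ac1 = np.dot(res[:-1], res[1:]) / denom  # biased normalisation
    return float(ac1), float(denom / n)


def rolling_ews(s, t=None, window: int = WINDOW) -> EWSSeries:
    """Rolling detrended lag-1 autocorrelation and variance.

    ``s`` may be a :class:`~somnifold.statespace.SleepDistanceSeries` or a
    plain array (then ``t`` supplies times, defaulting to the 3-s hop).
    Windows are trailing; the output is ``window - 1`` samples shorter
    than the input; any NaN inside a window yields NaN there.
    """
    if hasattr(s, "s"):
        t = np.asarray(s.t, float)
        x = np.asarray(s.s, float)
    else:
        x = np.asarray(s, dtype=float)
        t = np.arange(len(x)) * 3.0 if t is None else np.asarray(t, float)
    if len(x) <= window:
        raise ValueError("series must be longer than the window")
    n_out = len(x) - window + 1
    ac = np.empty(n_out)
    var = np.empty(n_out)
    for i in range(n_out):
        w = x[i:i + window]
        if not np.all(np.isfinite(w)):
            ac[i] = var[i] = np.nan
            continue
        ac[i], var[i] = _window_ews(w)
    return EWSSeries(t[window - 1:], ac, var, np.sqrt(var), window)


def trend_test(ews_list: list[EWSSeries] | list, which: str = "autocorr",
               stride: int = 1):
    """Mixed-model test for a time trend in an EWS index across subjects.

    Fits ``ews ~ time`` with a random intercept per subject; a
    significantly positive time coefficient is the critical-slowing-down
    signature.  Returns ``(slope, F, p, fallback_used)``; on a singular
    mixed fit it falls back to a one-sample t-test of the per-subject OLS
    slopes against zero (flagged by ``fallback_used``).

    ``stride`` subsamples each EWS series before testing.  Rolling windows
    overlap, so consecutive EWS values are strongly serially dependent and
    an i.i.d.-error model at stride 1 is anticonservative; ``stride``
    equal to the window length (100) keeps roughly independent values and
    restores a near-nominal false-positive rate on stationary series.
    """
    rows = []
    for sid, e in enumerate(ews_list):
        vals = getattr(e, which) if hasattr(e, which) else np.asarray(e)
        tt = e.t if hasattr(e, "t") else np.arange(len(vals)) * 3.0
        vals = np.asarray(vals)[::stride]
        tt = np.asarray(tt, float)[::stride]
        ok = np.isfinite(vals)
        rows.append(pd.DataFrame({"y": vals[ok],
                                  "time": tt[ok] / 60.0,
                                  "subject": sid}))
    df = pd.concat(rows, ignore_index=True)
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    try:
        import statsmodels.formula.api as smf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("y ~ time", df, groups=df["subject"]).fit(
                method="lbfgs")
        slope = float(model.params["time"])
        z = float(model.tvalues["time"])
        p = float(model.pvalues["time"])
        if not np.isfinite(p):
            raise np.linalg.LinAlgError("non-finite mixed-model p-value")
        return slope, z**2, p, False
    except Exception:
        from scipy import stats as sp_stats
        slopes = []
        for sid, g in df.groupby("subject"):
            if len(g) > 2 and g["time"].nunique() > 1:
                slopes.append(np.polyfit(g["time"], g["y"], 1)[0])
        res = sp_stats.ttest_1samp(slopes, 0.0)
        return float(np.mean(slopes)), float(res.statistic**2), \
            float(res.pvalue), True
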