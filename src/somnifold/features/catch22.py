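"""The CATCH-22 canonical time-series feature set.

Implemented from the published feature definitions (the 22 features
distilled from the hctsa library by Lubba et al.).  Each epoch is z-scored
before evaluation, as the canonical set assumes; a constant epoch returns
the defined degenerate values rather than raising.  Names follow the
canonical identifiers so downstream registries and the published feature
tables line up.

Two of the canonical features carry field aliases used in this package's
registry: ``SB_BinaryStats_mean_longstretch1`` is the "dwelling time"
(longest stretch of samples above the mean) and
``FC_LocalSimple_mean3_stderr`` is the "prediction error" (local-mean
forecast residual spread).
"""

from __future__ import annotations

import numpy as np

from . import _fast

__all__ = ["CATCH22_NAMES", "catch22_features"]

CATCH22_NAMES = [
    "DN_HistogramMode_5",
    "DN_HistogramMode_10",
    "CO_f1ecac",
    "CO_FirstMin_ac",
    "CO_HistogramAMI_even_2_5",
    "CO_trev_1_num",
    "MD_hrv_classic_pnn40",
    "SB_BinaryStats_mean_longstretch1",
    "SB_TransitionMatrix_3ac_sumdiagcov",
    "PD_PeriodicityWang_th0_01",
    "CO_Embed2_Dist_tau_d_expfit_meandiff",
    "IN_AutoMutualInfoStats_40_gaussian_fmmi",
    "FC_LocalSimple_mean1_tauresrat",
    "DN_OutlierInclude_p_001_mdrmd",
    "DN_OutlierInclude_n_001_mdrmd",
    "SP_Summaries_welch_rect_area_5_1",
    "SB_BinaryStats_diff_longstretch0",
    "SB_MotifThree_quantile_hh",
    "SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1",
    "SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1",
    "SP_Summaries_welch_rect_centroid",
    "FC_LocalSimple_mean3_stderr",
]


# -- helpers ----------------------------------------------------------------

def _acf(y: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Biased sample autocorrelation via FFT (acf[0] = 1)."""
    n = len(y)
    yc = y - y.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n - 1)))
    f = np.fft.rfft(yc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    if acov[0] <= 0:
        return np.ones(1 if max_lag is None else max_lag + 1)
    acf = acov / acov[0]
    return acf if max_lag is None else acf[: max_lag + 1]


def _first_zero_ac(acf: np.ndarray) -> int:
    """Lag of the first negative-going zero crossing of the ACF."""
    below = np.flatnonzero(acf[1:] < 0)
    return int(below[0] + 1) if len(below) else len(acf)


def _longest_run(bits: np.ndarray, value: bool) -> int:
    best = cur = 0
    for b in bits:
        cur = cur + 1 if b == value else 0
        best = max(best, cur)
    return best


def _histogram_mode(y: np.ndarray, n_bins: int) -> float:
    counts, edges = np.histogram(y, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(np.mean(centers[counts == counts.max()]))


def _linfit_sse(x: np.ndarray, y: np.ndarray) -> float:
    """Residual SSE of an OLS line through (x, y)."""
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        return float(np.sum((y - ym) ** 2))
    b = np.sum((x - xm) * (y - ym)) / sxx
    res = y - ym - b * (x - xm)
    return float(np.sum(res**2))


def _two_segment_prop_r1(log_tau: np.ndarray, log_f: np.ndarray) -> float:
    """Split the log-log fluctuation plot into two linear regimes at the
    point minimising the combined squared error; return the fraction of
    scales in the first regime (each regime needs >= 3 points)."""
    ntau = len(log_tau)
    if ntau < 6:
        return np.nan
    best_sse, best_k = np.inf, 3
    for k in range(3, ntau - 2):
        sse = (_linfit_sse(log_tau[:k], log_f[:k])
               + _linfit_sse(log_tau[k - 1:], log_f[k - 1:]))
        if sse < best_sse:
            best_sse, best_k = sse, k
    return best_k / ntau


def _fluct_scales(n: int, n_scales: int = 50) -> np.ndarray:
    lo, hi = 5, max(n // 2, 6)
    taus = np.unique(np.round(np.logspace(np.log10(lo), np.log10(hi),
                                          n_scales)).astype(int))
    return taus[taus >= 5]


def _fluct_anal(y: np.ndarray, how: str) -> float:
    """Fluctuation analysis of the cumulative sum; ``how`` in
    {'dfa', 'rsrange'}; returns the two-regime split proportion."""
    x = np.cumsum(y - y.mean())
    taus = _fluct_scales(len(y))
    f = _fast.fluct_f(x, taus, how == "dfa")
    good = np.isfinite(f) & (f > 0)
    if good.sum() < 6:
        return np.nan
    return float(_fast.two_segment_prop_r1(
        np.log(taus[good].astype(float)), np.log(f[good])))


def _welch_rect(y: np.ndarray):
    """Single-segment rectangular-window periodogram over angular frequency
    (rad/sample); returns (omega, S)."""
    n = len(y)
    nfft = int(2 ** np.ceil(np.log2(n)))
    spec = np.fft.rfft(y - y.mean(), nfft)
    s = (spec.real**2 + spec.imag**2) / (n * 2 * np.pi)
    omega = np.linspace(0, np.pi, len(s))
    return omega, s


def _spline_detrend(y: np.ndarray) -> np.ndarray:
    """Remove a two-piece cubic-spline trend (one interior knot)."""
    from scipy.interpolate import LSQUnivariateSpline
    n = len(y)
    t = np.arange(n, dtype=float)
    spl = LSQUnivariateSpline(t, y, [n / 2.0], k=3)
    return y - spl(t)


# -- the 22 features --------------------------------------------------------

def catch22_features(epoch: np.ndarray) -> dict[str, float]:
    """Evaluate the 22 canonical features on one epoch.

    Non-finite input yields a NaN vector; a constant epoch yields the
    degenerate values defined by each feature (no exception).
    """
    y_raw = np.asarray(epoch, dtype=float)
    if not np.all(np.isfinite(y_raw)):
        return {name: np.nan for name in CATCH22_NAMES}
    n = len(y_raw)
    sd = y_raw.std()
    y = (y_raw - y_raw.mean()) / sd if sd > 0 else y_raw - y_raw.mean()
    out: dict[str, float] = {}

    out["DN_HistogramMode_5"] = _histogram_mode(y, 5)
    out["DN_HistogramMode_10"] = _histogram_mode(y, 10)

    acf = _acf(y)
    # CO_f1ecac: linearly-interpolated first crossing of 1/e
    thr = 1.0 / np.e
    f1ecac = float(n)
    for i in range(len(acf) - 1):
        if acf[i + 1] < thr:
            f1ecac = i + (acf[i] - thr) / (acf[i] - acf[i + 1]) \
                if acf[i] != acf[i + 1] else float(i)
            break
    out["CO_f1ecac"] = f1ecac

    fm = float(n)
    for i in range(1, len(acf) - 1):
        if acf[i] < acf[i - 1] and acf[i] < acf[i + 1]:
            fm = float(i)
            break
    out["CO_FirstMin_ac"] = fm

    # CO_HistogramAMI_even_2_5: AMI at lag 2, 5 even bins over the range
    tau = 2
    x1, x2 = y[:-tau], y[tau:]
    lo, hi = y.min(), y.max()
    edges = np.linspace(lo - 0.1, hi + 0.1, 6)
    joint, *_ = np.histogram2d(x1, x2, bins=[edges, edges])
    pj = joint / joint.sum()
    px = pj.sum(axis=1, keepdims=True)
    py = pj.sum(axis=0, keepdims=True)
    nz = pj > 0
    out["CO_HistogramAMI_even_2_5"] = float(
        np.sum(pj[nz] * np.log(pj[nz] / (px @ py)[nz])))

    out["CO_trev_1_num"] = float(np.mean(np.diff(y) ** 3))
    out["MD_hrv_classic_pnn40"] = float(np.mean(np.abs(np.diff(y)) > 0.04))
    out["SB_BinaryStats_mean_longstretch1"] = float(_fast.longest_run(
        (y > y.mean()).astype(np.uint8), np.uint8(1)))

    # SB_TransitionMatrix_3ac_sumdiagcov
    tau_z = max(_first_zero_ac(acf), 1)
    yd = y[::tau_z]
    if len(yd) >= 4 and np.ptp(yd) > 0:
        qs = np.quantile(yd, [1 / 3, 2 / 3])
        sym = np.digitize(yd, qs)
        T = np.zeros((3, 3))
        for a, b in zip(sym[:-1], sym[1:]):
            T[a, b] += 1
        T /= max(len(sym) - 1, 1)
        cov = np.cov(T.T)
        out["SB_TransitionMatrix_3ac_sumdiagcov"] = float(np.trace(cov))
    else:
        out["SB_TransitionMatrix_3ac_sumdiagcov"] = np.nan

    # PD_PeriodicityWang_th0_01
    try:
        resid = _spline_detrend(y)
        acf_r = _acf(resid, max_lag=min(n - 2, n // 3))
        th = 0.01
        period = 0.0
        trough = None
        for i in range(1, len(acf_r) - 1):
            if acf_r[i] < acf_r[i - 1] and acf_r[i] < acf_r[i + 1]:
                trough = i
            elif trough is not None and acf_r[i] > acf_r[i - 1] \
                    and acf_r[i] > acf_r[i + 1]:
                if acf_r[i] > 0 and acf_r[i] - acf_r[trough] >= th:
                    period = float(i)
                    break
        out["PD_PeriodicityWang_th0_01"] = period
    except Exception:
        out["PD_PeriodicityWang_th0_01"] = np.nan

    # CO_Embed2_Dist_tau_d_expfit_meandiff
    tau_e = min(max(_first_zero_ac(acf), 1), max(n // 10, 1))
    emb_x, emb_y = y[:-tau_e], y[tau_e:]
    d = np.hypot(np.diff(emb_x), np.diff(emb_y))
    if len(d) > 1 and d.mean() > 0:
        scale = d.mean()
        counts, edges = np.histogram(d, bins="auto", density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        pdf = np.exp(-centers / scale) / scale
        out["CO_Embed2_Dist_tau_d_expfit_meandiff"] = float(
            np.mean(np.abs(counts - pdf)))
    else:
        out["CO_Embed2_Dist_tau_d_expfit_meandiff"] = np.nan

    # IN_AutoMutualInfoStats_40_gaussian_fmmi
    max_tau = min(40, n // 2 - 1)
    ami = _fast.ami_gaussian(y, max_tau)
    fmmi = float(max_tau)
    for i in range(1, max_tau - 1):
        if ami[i] < ami[i - 1] and ami[i] < ami[i + 1]:
            fmmi = float(i + 1)
            break
    out["IN_AutoMutualInfoStats_40_gaussian_fmmi"] = fmmi

    # FC_LocalSimple_mean1_tauresrat
    res1 = y[1:] - y[:-1]
    tau_res = _first_zero_ac(_acf(res1))
    out["FC_LocalSimple_mean1_tauresrat"] = tau_res / max(_first_zero_ac(acf), 1)

    out["DN_OutlierInclude_p_001_mdrmd"] = float(_fast.outlier_mdrmd(y, 0.01))
    out["DN_OutlierInclude_n_001_mdrmd"] = float(_fast.outlier_mdrmd(-y, 0.01))

    omega, s = _welch_rect(y)
    total = np.trapezoid(s, omega)
    if total > 0:
        fifth = len(s) // 5
        out["SP_Summaries_welch_rect_area_5_1"] = float(
            np.trapezoid(s[:fifth], omega[:fifth]))
        csum = np.cumsum(s)
        half_idx = int(np.searchsorted(csum, 0.5 * csum[-1]))
        out["SP_Summaries_welch_rect_centroid"] = float(
            omega[min(half_idx, len(omega) - 1)])
    else:
        out["SP_Summaries_welch_rect_area_5_1"] = np.nan
        out["SP_Summaries_welch_rect_centroid"] = np.nan

    out["SB_BinaryStats_diff_longstretch0"] = float(_fast.longest_run(
        (np.diff(y) >= 0).astype(np.uint8), np.uint8(0)))

    # SB_MotifThree_quantile_hh: entropy of successive 3-letter pairs
    if np.ptp(y) > 0:
        qs = np.quantile(y, [1 / 3, 2 / 3])
        sym = np.digitize(y, qs)
        pairs = sym[:-1] * 3 + sym[1:]
        counts = np.bincount(pairs, minlength=9).astype(float)
        p = counts / counts.sum()
        nzp = p > 0
        out["SB_MotifThree_quantile_hh"] = float(-np.sum(p[nzp] * np.log(p[nzp])))
    else:
        out["SB_MotifThree_quantile_hh"] = 0.0

    out["SC_FluctAnal_2_rsrangefit_50_1_logi_prop_r1"] = _fluct_anal(y, "rsrange")
    out["SC_FluctAnal_2_dfa_50_1_2_logi_prop_r1"] = _fluct_anal(y, "dfa")

    # FC_LocalSimple_mean3_stderr ("prediction error")
    w = 3
    if n > w + 1:
        pred = np.convolve(y, np.ones(w) / w, mode="valid")[:-1]
        res3 = y[w:] - pred
        out["FC_LocalSimple_mean3_stderr"] = float(np.std(res3, ddof=1))
    else:
        out["FC_LocalSimple_mean3_stderr"] = np.nan

    return {name: out[name] for name in CATCH22_NAMES}


def _outlier_include(y: np.ndarray, inc: float = 0.01) -> float:
    """Median relative position of threshold exceedances, medianised over
    thresholds (DN_OutlierInclude mdrmd)."""
    n = len(y)
    top = y.max()
    if top <= 0:
        return 0.0
    thresholds = np.arange(0, top + inc, inc)
    mdrs = []
    for th in thresholds:
        r = np.flatnonzero(y >= th)
        if len(r) < 2:
            break
        mdrs.append(np.median(r) / (n / 2) - 1)
    return float(np.median(mdrs)) if mdrs else 0.0
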