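"""Numba-compiled inner loops for the per-epoch features.

These are straight transcriptions of the reference loops in
:mod:`.catch22` and :mod:`.complexity`; they exist only for speed and are
cross-checked against the pure-Python definitions in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["outlier_mdrmd", "longest_run", "lz76", "two_segment_prop_r1",
           "ami_gaussian"]


@njit(cache=True)
def outlier_mdrmd(y: np.ndarray, inc: float) -> float:
    """DN_OutlierInclude mdrmd: median (over thresholds) of the median
    relative time position of samples exceeding the threshold."""
    n = len(y)
    top = np.max(y)
    if top <= 0:
        return 0.0
    order = np.argsort(-y)  # indices, descending by value
    vals_desc = y[order]
    n_th = int(top / inc) + 1
    mdrs = np.empty(n_th)
    cnt = 0
    for j in range(n_th):
        th = j * inc
        # k = number of samples >= th
        k = 0
        for i in range(n):
            if vals_desc[i] >= th:
                k += 1
            else:
                break
        if k < 2:
            break
        mdrs[cnt] = np.median(order[:k]) / (n / 2.0) - 1.0
        cnt += 1
    if cnt == 0:
        return 0.0
    return float(np.median(mdrs[:cnt]))


@njit(cache=True)
def longest_run(bits: np.ndarray, value: np.uint8) -> int:
    best = 0
    cur = 0
    for i in range(len(bits)):
        if bits[i] == value:
            cur += 1
            if cur > best:
                best = cur
        else:
            cur = 0
    return best


@njit(cache=True)
def lz76(s: np.ndarray) -> int:
    """Lempel-Ziv-76 phrase count (Kaspar-Schuster scan) of a 0/1 array."""
    n = len(s)
    i = 0
    k = 1
    l = 1
    k_max = 1
    c = 1
    while True:
        if l + k > n:
            c += 1
            break
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c


@njit(cache=True)
def _linfit_sse(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    xm = np.mean(x)
    ym = np.mean(y)
    sxx = 0.0
    sxy = 0.0
    for i in range(n):
        dx = x[i] - xm
        sxx += dx * dx
        sxy += dx * (y[i] - ym)
    if sxx == 0.0:
        sse = 0.0
        for i in range(n):
            d = y[i] - ym
            sse += d * d
        return sse
    b = sxy / sxx
    sse = 0.0
    for i in range(n):
        r = y[i] - ym - b * (x[i] - xm)
        sse += r * r
    return sse


@njit(cache=True)
def two_segment_prop_r1(log_tau: np.ndarray, log_f: np.ndarray) -> float:
    """Fraction of scales in the first of two linear regimes of the
    log-log fluctuation plot (split minimising total squared error)."""
    ntau = len(log_tau)
    if ntau < 6:
        return np.nan
    best_sse = 1e300
    best_k = 3
    for k in range(3, ntau - 2):
        sse = (_linfit_sse(log_tau[:k], log_f[:k])
               + _linfit_sse(log_tau[k - 1:], log_f[k - 1:]))
        if sse < best_sse:
            best_sse = sse
            best_k = k
    return best_k / ntau


@njit(cache=True)
def fluct_f(x: np.ndarray, taus: np.ndarray, dfa: bool) -> np.ndarray:
    """Fluctuation function F(tau) of a cumulative-sum walk ``x``:
    per-window linear detrend, then residual RMS (dfa) or mean residual
    range (rsrange), averaged over non-overlapping windows."""
    out = np.empty(len(taus))
    for s in range(len(taus)):
        tau = taus[s]
        n_win = len(x) // tau
        if n_win < 2:
            out[s] = np.nan
            continue
        tm = (tau - 1) / 2.0
        stt = 0.0
        for i in range(tau):
            stt += (i - tm) ** 2
        acc = 0.0
        for w in range(n_win):
            base = w * tau
            wm = 0.0
            for i in range(tau):
                wm += x[base + i]
            wm /= tau
            sxy = 0.0
            for i in range(tau):
                sxy += (i - tm) * (x[base + i] - wm)
            b = sxy / stt
            if dfa:
                ss = 0.0
                for i in range(tau):
                    r = x[base + i] - wm - b * (i - tm)
                    ss += r * r
                acc += ss
            else:
                rmax = -1e300
                rmin = 1e300
                for i in range(tau):
                    r = x[base + i] - wm - b * (i - tm)
                    if r > rmax:
                        rmax = r
                    if r < rmin:
                        rmin = r
                acc += rmax - rmin
        if dfa:
            out[s] = np.sqrt(acc / (n_win * tau))
        else:
            out[s] = acc / n_win
    return out


@njit(cache=True)
def ami_gaussian(y: np.ndarray, max_tau: int) -> np.ndarray:
    """Gaussian auto-mutual information -0.5 log(1 - rho_k^2), k=1..max_tau."""
    out = np.empty(max_tau)
    n = len(y)
    for k in range(1, max_tau + 1):
        m = n - k
        mx = 0.0
        my = 0.0
        for i in range(m):
            mx += y[i]
            my += y[i + k]
        mx /= m
        my /= m
        sxy = 0.0
        sxx = 0.0
        syy = 0.0
        for i in range(m):
            dx = y[i] - mx
            dy = y[i + k] - my
            sxy += dx * dy
            sxx += dx * dx
            syy += dy * dy
        denom = np.sqrt(sxx * syy)
        if denom <= 0.0:
            out[k - 1] = 0.0
            continue
        rho = sxy / denom
        rho2 = rho * rho
        if rho2 > 1.0 - 1e-12:
            rho2 = 1.0 - 1e-12
        out[k - 1] = -0.5 * np.log(1.0 - rho2)
    return out
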