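"""Functional PCA of group-averaged feature time series.

The ensemble of feature curves (one curve per EEG feature over the
pre-onset time grid) is decomposed into functional principal components:
each curve is ridge-smoothed (Whittaker second-difference penalty) and the
smoothed ensemble, centred on the mean curve, is decomposed by ordinary
PCA with trapezoidal quadrature weights on the time grid.  Components are
rendered as mean +/- component; per-feature scores are the loadings, with
scores normalised to [-1, 1] (positive scores divided by the maximum
positive score, negative by the magnitude of the minimum).

``control_parameter_match`` ranks features as proxies of the bifurcation
control parameter c(t) by |cosine similarity| / DTW distance.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

__all__ = ["FPCAResult", "FunctionalPCA", "fit_fpca",
           "representative_features", "control_parameter_match",
           "dtw_distance", "cosine_similarity"]


@dataclass
class FPCAResult:
    t: np.ndarray
    mean_curve: np.ndarray
    components: np.ndarray          # (n_components, n_time)
    explained_variance_ratio: np.ndarray
    scores: np.ndarray              # (n_curves, n_components)
    normalized_scores: np.ndarray   # same shape, in [-1, 1] per component
    curve_names: list[str]

    def rendered(self, k: int = 0) -> tuple[np.ndarray, np.ndarray]:
        """(mean + component_k, mean - component_k) display curves."""
        return (self.mean_curve + self.components[k],
                self.mean_curve - self.components[k])


def _whittaker_smooth(y: np.ndarray, lam: float) -> np.ndarray:
    """Ridge smoothing with a second-difference penalty (per curve row)."""
    n = y.shape[-1]
    if lam <= 0 or n < 3:
        return y
    D = np.diff(np.eye(n), n=2, axis=0)
    A = np.eye(n) + lam * D.T @ D
    return np.linalg.solve(A, y.T).T


class FunctionalPCA(BaseEstimator, TransformerMixin):
    """Discretised FPCA with ridge smoothing.

    Parameters
    ----------
    n_components : number of functional components to keep.
    ridge : Whittaker smoothing penalty applied to each curve before the
        decomposition (0 disables smoothing).
    """

    def __init__(self, n_components: int = 2, ridge: float = 1e-3):
        self.n_components = n_components
        self.ridge = ridge

    def fit(self, curves: np.ndarray, t=None, curve_names=None):
        curves = np.asarray(curves, dtype=float)
        if curves.ndim != 2:
            raise ValueError("curves must be (n_curves, n_time)")
        if curves.shape[0] < self.n_components:
            raise ValueError("fewer curves than requested components")
        if not np.all(np.isfinite(curves)):
            raise ValueError("curves must be NaN-free (use bootstrapped means)")
        t = np.arange(curves.shape[1], dtype=float) if t is None \
            else np.asarray(t, dtype=float)
        sm = _whittaker_smooth(curves, self.ridge)
        # trapezoidal quadrature weights turn the grid PCA into an L2 FPCA
        w = np.gradient(t)
        w[0] *= 0.5
        w[-1] *= 0.5
        sqw = np.sqrt(w / w.sum())
        self._sqw = sqw
        self._pca = PCA(n_components=self.n_components)
        scores = self._pca.fit_transform(sm * sqw)
        self.t_ = t
        self.mean_curve_ = self._pca.mean_ / sqw
        self.components_ = self._pca.components_ / sqw
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        self.scores_ = scores
        self.normalized_scores_ = self._normalize(scores)
        self.curve_names_ = list(curve_names) if curve_names is not None \
            else [f"curve_{i}" for i in range(curves.shape[0])]
        return self

    @staticmethod
    def _normalize(scores: np.ndarray) -> np.ndarray:
        out = np.zeros_like(scores)
        for k in range(scores.shape[1]):
            col = scores[:, k]
            pos = col > 0
            if pos.any():
                out[pos, k] = col[pos] / col[pos].max()
            if (~pos).any():
                neg = col <= 0
                mn = col[neg].min()
                if mn < 0:
                    out[neg, k] = -col[neg] / mn
        return out

    def transform(self, curves: np.ndarray) -> np.ndarray:
        sm = _whittaker_smooth(np.asarray(curves, dtype=float), self.ridge)
        return self._pca.transform(sm * self._sqw)

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return self._pca.inverse_transform(scores) / self._sqw

    @property
    def result_(self) -> FPCAResult:
        return FPCAResult(self.t_, self.mean_curve_, self.components_,
                          self.explained_variance_ratio_, self.scores_,
                          self.normalized_scores_, self.curve_names_)


def fit_fpca(curves, t=None, n_components: int = 2, ridge: float = 1e-3,
             curve_names=None) -> FPCAResult:
    """Functional wrapper over :class:`FunctionalPCA`."""
    est = FunctionalPCA(n_components=n_components, ridge=ridge)
    return est.fit(curves, t=t, curve_names=curve_names).result_


def representative_features(result: FPCAResult, component: int = 0,
                            threshold: float = 0.9):
    """Features whose normalised score exceeds +threshold (or -threshold),
    sorted by absolute normalised score (descending)."""
    ns = result.normalized_scores[:, component]
    pos = [(result.curve_names[i], ns[i]) for i in np.flatnonzero(ns >= threshold)]
    neg = [(result.curve_names[i], ns[i]) for i in np.flatnonzero(ns <= -threshold)]
    pos.sort(key=lambda kv: -abs(kv[1]))
    neg.sort(key=lambda kv: -abs(kv[1]))
    return pos, neg


# ---------------------------------------------------------------------------
# Control-parameter matching
# ---------------------------------------------------------------------------

def cosine_similarity(x: np.ndarray, c: np.ndarray) -> float:
    x = np.asarray(x, float)
    c = np.asarray(c, float)
    nx, nc = np.linalg.norm(x), np.linalg.norm(c)
    if nx == 0 or nc == 0:
        return np.nan
    return float(np.dot(x, c) / (nx * nc))


from numba import njit


@njit(cache=True)
def _dtw_core(x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    m = len(y)
    prev = np.full(m + 1, np.inf)
    prev[0] = 0.0
    cur = np.empty(m + 1)
    for i in range(1, n + 1):
        cur[0] = np.inf
        for j in range(1, m + 1):
            c = abs(x[i - 1] - y[j - 1])
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        prev, cur = cur, prev
    return prev[m]


def dtw_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Classic dynamic time warping with unit (symmetric) steps and
    absolute-difference local cost."""
    x = np.ascontiguousarray(x, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    return float(_dtw_core(x, y))


def control_parameter_match(curves: np.ndarray, c_t: np.ndarray,
                            curve_names=None):
    """Rank features as control-parameter proxies.

    For each feature curve: metric = |cosine(x, c)| / DTW(x, c); the
    feature with the highest metric best mirrors the fitted control ramp.
    Zero-norm curves are excluded with a warning.  Returns
    ``(table, best_name)`` with table rows
    ``(name, |cosine|, dtw, metric)`` sorted by metric descending.
    """
    curves = np.atleast_2d(np.asarray(curves, float))
    c_t = np.asarray(c_t, float)
    if curves.shape[1] != len(c_t):
        raise ValueError("curves and c(t) must share the time grid")
    names = list(curve_names) if curve_names is not None \
        else [f"curve_{i}" for i in range(curves.shape[0])]
    table = []
    for name, x in zip(names, curves):
        if np.linalg.norm(x) == 0:
            warnings.warn(f"zero-norm curve {name!r} excluded")
            continue
        cos = abs(cosine_similarity(x, c_t))
        d = dtw_distance(x, c_t)
        metric = cos / d if d > 0 else np.inf
        table.append((name, cos, d, metric))
    if not table:
        raise ValueError("no usable curves")
    table.sort(key=lambda r: -r[3])
    return table, table[0][0]
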