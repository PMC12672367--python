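"""Fold (saddle-node) bifurcation model of the falling-asleep transition.

The sleep distance ``s(t)`` — the Euclidean distance of the instantaneous
EEG feature vector from the sleep-onset centroid — is modelled as the state
``x`` of an overexploitation-type resource system

    dx/dt = r * x * (1 - x/K) - c * x**2 / (x**2 + h**2)

with a control parameter ``c`` that ramps linearly in time,
``c(t) = c0 + m*t``.  ``r`` is a restoring (growth) rate, ``K`` the carrying
capacity (maximal bedtime sleep distance, in s.d. units), ``h`` a
half-saturation scale of the reduction drive and ``m`` the ramp rate of the
sleep drive.  For suitable parameters the system has a bistable zone in
``c`` bounded above by a fold: when ``c(t)`` crosses the fold value the
upper (wake) equilibrium annihilates with the unstable branch and the state
collapses to the lower (sleep) branch — the wake-to-sleep tipping point.

``BifurcationModel`` fits this model to an observed ``s(t)`` trace with the
sequential grid search described in :meth:`BifurcationModel.fit`, and
derives the bifurcation diagram and tipping point from the fitted
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from sklearn.base import BaseEstimator

__all__ = [
    "BifurcationParams",
    "BifurcationDiagram",
    "BifurcationModel",
    "rhs",
    "simulate_model",
    "equilibria",
    "bifurcation_diagram",
    "fit",
    "tipping_point",
]


@dataclass
class BifurcationParams:
    """Parameters of the fold-bifurcation model.

    All rates are per minute when ``t`` is in minutes; ``K``, ``h`` and the
    state are in the units of the fitted series (s.d. for sleep distance).
    """

    r: float
    K: float
    h: float
    m: float
    c0: float = 1.0
    x0: float | None = None

    def validate(self) -> None:
        if not (self.r > 0 and self.K > 0 and self.h > 0 and self.m >= 0):
            raise ValueError("require r, K, h > 0 and m >= 0")
        if self.c0 < 0:
            raise ValueError("require c0 >= 0")


@dataclass
class BifurcationDiagram:
    """Equilibrium branches of the model over a grid of control values.

    ``branches`` holds ``(c, x_eq, stability)`` samples for the positive
    equilibria; ``x = 0`` (always an equilibrium) is reported separately via
    ``zero_stability``.  ``fold`` is the (c*, x*) point where the upper
    stable branch and the unstable branch merge — the tipping point of the
    transition.  ``three_solution_range`` is the interval of ``c`` with
    three positive equilibria (the bistable/critical zone).
    """

    c_grid: np.ndarray
    branches: list[tuple[float, float, str]]
    fold: tuple[float, float] | None
    three_solution_range: tuple[float, float] | None
    zero_stability: str = "stable"

    @property
    def has_fold(self) -> bool:
        return self.fold is not None


def rhs(x, c, params: BifurcationParams):
    """Model right-hand side dx/dt at state ``x`` and control ``c``."""
    x = np.asarray(x, dtype=float)
    return params.r * x * (1.0 - x / params.K) - c * x * x / (x * x + params.h**2)


def _drhs_dx(x: float, c: float, p: BifurcationParams) -> float:
    # d/dx [ r x (1 - x/K) - c x^2/(x^2+h^2) ]
    h2 = p.h**2
    return p.r * (1.0 - 2.0 * x / p.K) - c * 2.0 * x * h2 / (x * x + h2) ** 2


def simulate_model(params: BifurcationParams, t_grid, rtol: float = 1e-6,
                   atol: float = 1e-9) -> np.ndarray:
    """Integrate the model with the linear control ramp c(t) = c0 + m*t.

    Uses an adaptive explicit (non-stiff) solver; the state is clipped at
    zero from below.  ``t_grid`` must be increasing; ``params.x0`` is the
    initial state (defaults to K).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a 1-d increasing array")
    params.validate()
    x0 = params.K if params.x0 is None else float(params.x0)

    def f(t, y):
        x = max(y[0], 0.0)
        c = params.c0 + params.m * t
        return [params.r * x * (1.0 - x / params.K)
                - c * x * x / (x * x + params.h**2)]

    sol = solve_ivp(f, (t_grid[0], t_grid[-1]), [x0], method="RK45",
                    t_eval=t_grid, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    return np.clip(sol.y[0], 0.0, None)


def equilibria(c: float, params: BifurcationParams) -> list[tuple[float, str]]:
    """All nonnegative equilibria of the model at fixed control ``c``.

    ``x = 0`` is always a root; the others solve the cubic
    ``r (1 - x/K) (x^2 + h^2) - c x = 0``.  Stability follows the sign of
    the state derivative of the right-hand side at the root.
    """
    if c < 0:
        raise ValueError("c must be >= 0")
    p = params
    # -(r/K) x^3 + r x^2 - (r h^2/K + c) x + r h^2 = 0
    coeffs = [-p.r / p.K, p.r, -(p.r * p.h**2 / p.K + c), p.r * p.h**2]
    roots = np.roots(coeffs)
    out: list[tuple[float, str]] = [(0.0, _stability(0.0, c, p))]
    for z in roots:
        if abs(z.imag) < 1e-9 and z.real > 1e-12:
            out.append((float(z.real), _stability(float(z.real), c, p)))
    out.sort(key=lambda rc: rc[0])
    return out


def _stability(x: float, c: float, p: BifurcationParams) -> str:
    return "stable" if _drhs_dx(x, c, p) < 0 else "unstable"


def bifurcation_diagram(params: BifurcationParams, c_range=(0.0, 10.0),
                        c_step: float = 1e-3,
                        refine_tol: float = 1e-9) -> BifurcationDiagram:
    """Scan control values for the equilibrium branches and the fold.

    The fold (c*, x*) is taken at the upper end of the range of ``c`` with
    three positive equilibria, refined by bisection on the positive-root
    count to ``refine_tol`` in ``c``.
    """
    c_lo, c_hi = float(c_range[0]), float(c_range[1])
    c_grid = np.arange(c_lo, c_hi + c_step / 2, c_step)
    branches: list[tuple[float, float, str]] = []
    n_pos = np.empty(len(c_grid), dtype=int)
    for i, c in enumerate(c_grid):
        eqs = [e for e in equilibria(float(c), params) if e[0] > 0]
        n_pos[i] = len(eqs)
        for x_eq, stab in eqs:
            branches.append((float(c), x_eq, stab))

    idx3 = np.flatnonzero(n_pos == 3)
    if len(idx3) == 0:
        return BifurcationDiagram(c_grid, branches, None, None)

    c_last3 = c_grid[idx3[-1]]
    c_first3 = c_grid[idx3[0]]
    # refine the fold by bisection on the positive-root count
    lo, hi = c_last3, min(c_last3 + c_step, c_hi)
    while hi - lo > refine_tol:
        mid = 0.5 * (lo + hi)
        if sum(1 for e in equilibria(mid, params) if e[0] > 0) == 3:
            lo = mid
        else:
            hi = mid
    c_fold = 0.5 * (lo + hi)
    eqs = sorted(e[0] for e in equilibria(max(lo - 1e-12, c_last3), params)
                 if e[0] > 0)
    # merging branches are the upper two (unstable middle meets upper stable)
    x_fold = 0.5 * (eqs[-1] + eqs[-2]) if len(eqs) >= 2 else eqs[-1]
    return BifurcationDiagram(c_grid, branches, (float(c_fold), float(x_fold)),
                              (float(c_first3), float(c_fold)))


class BifurcationModel(BaseEstimator):
    """Grid-search fit of the fold-bifurcation model to a sleep-distance trace.

    The fitting procedure:

    1. initial parameters (given or heuristic) are required to bifurcate
       within the trace's time range;
    2. ``K`` is set to the mean of the first 100 values of ``s(t)`` (fewer
       if the trace is shorter), with ``r`` and ``m`` rescaled inversely to
       the ``K`` change so the fold stays inside the window;
    3. a ``K`` grid (+0.25 per step, 10 steps, same rescaling) keeps the
       value maximising R^2;
    4. sequential hill-climb on ``r`` (step 0.02), ``m`` (0.005) and ``h``
       (0.001), maximising the objective R^2 - RMSE, up to 250 iterations
       per parameter; the sweep repeats for up to ``n_sweeps`` rounds while
       it improves, and the whole search is multi-started over a small grid
       of initial ramp rates (``m_multistart``), keeping the best objective;
    5. the bifurcation diagram is built from the best parameters; the
       tipping time solves ``c(t*) = c*``.

    R^2 uses an uncentred total sum of squares (sum of squared target
    values) by default; set ``centered_r2=True`` for the conventional
    definition.  ``symmetric_k_search=True`` also scans decreasing ``K``.

    Attributes (after fit): ``params_``, ``fitted_``, ``r2_``, ``rmse_``,
    ``objective_``, ``diagram_``, ``tipping_time_``, ``critical_distance_``,
    ``critical_control_``, ``failed_``, ``failure_reason_``.
    """

    K_STEP = 0.25
    K_ITER = 10
    STEPS = {"r": 0.02, "m": 0.005, "h": 0.001}
    COORD_ITER = 250

    def __init__(self, init: BifurcationParams | None = None,
                 centered_r2: bool = False, symmetric_k_search: bool = False,
                 rtol: float = 1e-6,
                 m_multistart: tuple = (0.7, 0.85, 1.0, 1.15, 1.3),
                 n_sweeps: int = 2):
        self.init = init
        self.centered_r2 = centered_r2
        self.symmetric_k_search = symmetric_k_search
        self.rtol = rtol
        self.m_multistart = m_multistart
        self.n_sweeps = n_sweeps

    # -- objective ---------------------------------------------------------

    def _score_cached(self, t, s, p: BifurcationParams):
        key = (round(p.r, 9), round(p.K, 9), round(p.h, 9), round(p.m, 9))
        hit = self._memo.get(key)
        if hit is None:
            hit = self._score(t, s, p)
            self._memo[key] = hit
        return hit

    def _score(self, t, s, p: BifurcationParams):
        try:
            x = simulate_model(p, t, rtol=self.rtol)
        except (RuntimeError, ValueError):
            return -np.inf, -np.inf, np.inf, None
        res = s - x
        rss = float(np.sum(res**2))
        tss = float(np.sum((s - s.mean()) ** 2)) if self.centered_r2 \
            else float(np.sum(s**2))
        r2 = 1.0 - rss / tss if tss > 0 else -np.inf
        rmse = float(np.sqrt(np.mean(res**2)))
        return r2 - rmse, r2, rmse, x

    # -- fitting -----------------------------------------------------------

    def fit(self, t, s=None):
        """Fit to a trace.  ``t``: times (min, onset = 0, increasing);
        ``s``: sleep distance values.  Accepts ``fit(series)`` where
        ``series`` has ``.t`` (seconds) and ``.s`` attributes."""
        if s is None and hasattr(t, "s"):
            s = np.asarray(t.s, float)
            t = np.asarray(t.t, float) / 60.0
        t = np.asarray(t, dtype=float)
        s = np.asarray(s, dtype=float)
        keep = np.isfinite(s)
        t, s = t[keep], s[keep]
        if len(s) < 20:
            raise ValueError("need at least 20 finite samples to fit")
        if np.ptp(s) < 1e-12:
            return self._fail("degenerate (constant) input trace")

        # the ODE clock starts at the first trace sample: c(tau=0) = c0
        tau = t - t[0]
        n_head = min(100, len(s))
        K_est = float(np.mean(s[:n_head]))
        if K_est <= 0:
            return self._fail("nonpositive carrying-capacity estimate")
        x0 = float(np.mean(s[:min(20, len(s))]))

        self._memo: dict = {}
        if self.init is not None:
            p00 = self.init
            starts = [BifurcationParams(p00.r, p00.K, p00.h, p00.m,
                                        p00.c0, x0)]
        else:
            base = self._default_init(t, s, K_est, x0)
            # multi-start over the initial ramp rate: the collapse-time
            # estimate behind the heuristic m is coarse, and the sweep
            # below is local
            starts = [BifurcationParams(base.r, base.K, base.h, base.m * f,
                                        base.c0, x0)
                      for f in self.m_multistart]

        best_global = None
        for p0 in starts:
            # step 2: pin K to the head mean, rescale r and m inversely
            scale = p0.K / K_est
            p = BifurcationParams(p0.r * scale, K_est, p0.h, p0.m * scale,
                                  p0.c0, x0)
            # step 3: K grid, keeping the K with the highest R^2
            best_p, best_r2 = p, self._score_cached(tau, s, p)[1]
            k_dirs = (1.0, -1.0) if self.symmetric_k_search else (1.0,)
            for direction in k_dirs:
                for i in range(1, self.K_ITER + 1):
                    K_new = K_est + direction * i * self.K_STEP
                    if K_new <= 0:
                        break
                    sc = K_est / K_new  # inverse rescaling of the rates
                    cand = BifurcationParams(p.r * sc, K_new, p.h, p.m * sc,
                                             p.c0, x0)
                    r2 = self._score_cached(tau, s, cand)[1]
                    if r2 > best_r2:
                        best_p, best_r2 = cand, r2
            p = best_p

            # step 4: sequential coordinate hill-climb on r, m, h,
            # repeated up to n_sweeps rounds while it improves
            obj = self._score_cached(tau, s, p)[0]
            for _sweep in range(self.n_sweeps):
                improved = False
                for name in ("r", "m", "h"):
                    step = self.STEPS[name]
                    for _ in range(self.COORD_ITER):
                        moved = False
                        for sgn in (+1.0, -1.0):
                            cand = self._bump(p, name, sgn * step)
                            if cand is None:
                                continue
                            cobj = self._score_cached(tau, s, cand)[0]
                            if cobj > obj:
                                p, obj, moved, improved = cand, cobj, True, True
                                break
                        if not moved:  # local optimum in this coordinate
                            break
                if not improved:
                    break
            if best_global is None or obj > best_global[1]:
                best_global = (p, obj)

        p = best_global[0]
        objective, r2, rmse, x = self._score(tau, s, p)
        if x is None:
            return self._fail("model integration failed at the optimum")
        self.params_, self.r2_, self.rmse_, self.objective_ = p, r2, rmse, objective
        self.fitted_ = x
        self.t_, self.s_ = t, s
        self.control_ = p.c0 + p.m * tau

        c_max = p.c0 + p.m * tau[-1]
        diagram = bifurcation_diagram(
            p, c_range=(0.0, max(2.0 * c_max, 5.0)), c_step=1e-3)
        self.diagram_ = diagram
        if not diagram.has_fold:
            self.failed_ = True
            self.failure_reason_ = "no three-solution (critical) zone in the diagram"
            self.tipping_time_ = self.critical_distance_ = self.critical_control_ = np.nan
            return self
        c_star, x_star = diagram.fold
        self.critical_control_ = c_star
        self.critical_distance_ = x_star
        self.tipping_time_ = t[0] + (c_star - p.c0) / p.m if p.m > 0 else np.inf
        self.failed_ = False
        self.failure_reason_ = None
        return self

    def _bump(self, p: BifurcationParams, name: str, delta: float):
        val = getattr(p, name) + delta
        if val <= 0:
            return None
        q = BifurcationParams(p.r, p.K, p.h, p.m, p.c0, p.x0)
        setattr(q, name, val)
        return q

    def _default_init(self, t, s, K, x0) -> BifurcationParams:
        """Heuristic initial parameters that bifurcate within the trace.

        Time unit: minutes.  r = 1, h = K/10, c0 = 1; ``m`` is chosen so
        the fold control value is reached where the trace first drops
        through K/2 (the observed collapse), falling back to 85% of the
        trace span if it never does.
        """
        r, h, c0 = 1.0, K / 10.0, 1.0
        probe = BifurcationParams(r, K, h, m=1.0, c0=c0)
        dia = bifurcation_diagram(probe, c_range=(0.0, 20.0 * r), c_step=2e-2)
        c_star = dia.fold[0] if dia.has_fold else 2.0 * r
        n_sm = max(len(s) // 50, 1)
        smooth = np.convolve(s, np.ones(n_sm) / n_sm, mode="same")
        drops = np.flatnonzero(smooth < 0.5 * K)
        if len(drops):
            t_col = t[drops[0]]
        else:
            t_col = t[0] + 0.85 * (t[-1] - t[0])
        span = max(t_col - t[0], (t[-1] - t[0]) * 0.05)
        m = max((c_star - c0) / span, 1e-4)
        return BifurcationParams(r, K, h, m, c0, x0)

    def _fail(self, reason: str):
        self.failed_ = True
        self.failure_reason_ = reason
        self.params_ = None
        self.r2_ = self.rmse_ = self.objective_ = np.nan
        self.tipping_time_ = self.critical_distance_ = self.critical_control_ = np.nan
        self.diagram_ = None
        return self

    # -- tipping -----------------------------------------------------------

    def tipping_point(self, hypnogram=None, onset_time_s: float | None = None):
        """Tipping point of the fitted transition.

        Returns ``(t_star_min, x_star, c_star, stage_at_tipping, valid)``
        with ``t_star`` on the trace's clock (sleep onset = 0).  The
        prediction is valid only if the tipping point precedes sleep onset.
        ``hypnogram`` (with ``onset_time_s``, seconds from recording start)
        resolves the sleep stage at the tipping time.
        """
        if getattr(self, "failed_", True):
            raise RuntimeError(
                f"fit failed: {getattr(self, 'failure_reason_', 'not fitted')}")
        t_star = self.tipping_time_  # minutes on the trace clock
        stage = None
        if hypnogram is not None and onset_time_s is not None:
            abs_s = onset_time_s + t_star * 60.0
            idx = int(abs_s // hypnogram.epoch_len)
            if 0 <= idx < len(hypnogram.stages):
                stage = hypnogram.stages[idx]
        valid = bool(t_star <= 0)
        return t_star, self.critical_distance_, self.critical_control_, stage, valid


# -- thin functional wrappers ----------------------------------------------

def fit(series, init: BifurcationParams | None = None, **kwargs) -> BifurcationModel:
    """Fit the fold-bifurcation model to a sleep-distance series."""
    return BifurcationModel(init=init, **kwargs).fit(series)


def tipping_point(model: BifurcationModel, hypnogram=None, onset_time_s=None):
    return model.tipping_point(hypnogram, onset_time_s)
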