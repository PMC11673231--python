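"""Evaluation metrics for survival predictions.

Implements the time-dependent concordance index (Antolini's estimator, which
compares whole survival curves rather than a single risk score) and the
inverse-probability-of-censoring-weighted (IPCW) Brier score with its
integral over a follow-up window.  Predictions enter as a matrix of survival
probabilities S[i, k] = S(t_k | X_i) on an evaluation time grid; values at a
subject's own observed time are obtained by linear interpolation on that
grid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter


@dataclass
class KMCurve:
    """Right-continuous product-limit step function."""

    times: np.ndarray  # distinct observed times, ascending
    surv: np.ndarray  # S(t) just after each time
    n: int

    def predict(self, t) -> np.ndarray:
        """S(t), right-continuous (value after any jump at t)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        vals = np.concatenate([[1.0], self.surv])
        return vals[idx]

    def predict_left(self, t) -> np.ndarray:
        """S(t-), the left limit (value just before t)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left")
        vals = np.concatenate([[1.0], self.surv])
        return vals[idx]

    @property
    def median(self) -> float:
        below = self.times[self.surv <= 0.5]
        return float(below[0]) if len(below) else float("inf")


def km_estimator(time, event_flag) -> KMCurve:
    """Kaplan-Meier product-limit estimator of S(t).

    Pass ``1 - event`` as the flag to estimate the censoring distribution G
    instead (censorings treated as the "events" of interest).
    """
    time = np.asarray(time, dtype=float)
    event_flag = np.asarray(event_flag).astype(bool)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event_flag)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = t > 0
    return KMCurve(times=t[keep], surv=s[keep], n=len(time))


def _interp_at(S_matrix: np.ndarray, eval_times: np.ndarray, t) -> np.ndarray:
    """Linearly interpolate each row of S_matrix at times t -> (n, len(t))."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    tt = np.clip(t, eval_times[0], eval_times[-1])
    j = np.clip(np.searchsorted(eval_times, tt, side="left"), 1, len(eval_times) - 1)
    lo, hi = eval_times[j - 1], eval_times[j]
    u = (tt - lo) / np.where(hi > lo, hi - lo, 1.0)
    return S_matrix[:, j - 1] * (1.0 - u)[None, :] + S_matrix[:, j] * u[None, :]


def c_index_td(S_matrix, eval_times, time, event) -> float:
    """Time-dependent concordance index (Antolini's estimator).

    A pair (i, j) is comparable when t_i < t_j and d_i = 1, or when
    t_i = t_j with d_i = 1 and d_j = 0.  It is concordant when the
    earlier-failing subject has the lower predicted survival at its own
    event time, S_i(t_i) < S_j(t_i); ties in the predicted values score 0.5.
    Returns the concordant fraction over comparable pairs; 0.5 is chance
    level and 1 perfect concordance.
    """
    S_matrix = np.asarray(S_matrix, dtype=float)
    eval_times = np.asarray(eval_times, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    n = len(time)
    if S_matrix.shape != (n, len(eval_times)):
        raise ValueError("S_matrix must be (n subjects, len(eval_times))")

    # Sti[j, i] = S_j(t_i) for every subject j at every observed time t_i
    Sti = _interp_at(S_matrix, eval_times, time)
    own = np.diag(Sti)
    comparable = event[:, None] & (
        (time[:, None] < time[None, :])
        | ((time[:, None] == time[None, :]) & ~event[None, :])
    )
    np.fill_diagonal(comparable, False)
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    other = Sti.T  # other[i, j] = S_j(t_i)
    conc = (own[:, None] < other) + 0.5 * (own[:, None] == other)
    return float(conc[comparable].sum() / n_pairs)


def brier_score(S_matrix, eval_times, time, event, t_eval, G: KMCurve | None = None) -> float:
    """IPCW Brier score at a single time point.

    Subjects who failed by ``t_eval`` contribute ``S_i(t_eval)^2 / G(t_i-)``;
    subjects still under observation contribute ``(1 - S_i(t_eval))^2 /
    G(t_eval)``; subjects censored before ``t_eval`` contribute nothing.
    G is the Kaplan-Meier estimate of the censoring distribution.  Weights
    with G = 0 are capped (with a warning) rather than allowed to diverge.
    """
    S_matrix = np.asarray(S_matrix, dtype=float)
    eval_times = np.asarray(eval_times, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if G is None:
        G = km_estimator(time, ~event)
    S_t = _interp_at(S_matrix, eval_times, t_eval)[:, 0]

    failed = (time <= t_eval) & event
    at_risk = time > t_eval
    g_fail = np.asarray(G.predict_left(time), dtype=float)
    g_eval = float(G.predict(t_eval))
    cap = 1.0 / max(len(time), 1)
    if (np.any(g_fail[failed] < cap) and failed.any()) or (at_risk.any() and g_eval < cap):
        warnings.warn("censoring-survival weight near 0 capped", stacklevel=2)
    g_fail = np.maximum(g_fail, cap)
    g_eval = max(g_eval, cap)

    contrib = np.zeros(len(time))
    contrib[failed] = S_t[failed] ** 2 / g_fail[failed]
    contrib[at_risk] = (1.0 - S_t[at_risk]) ** 2 / g_eval
    return float(contrib.mean())


def integrated_brier_score(S_matrix, eval_times, time, event, grid=None) -> float:
    """Trapezoidal integral of BS(t) over a follow-up window, span-normalized.

    Default integration grid: 100 equispaced points from 0 to the maximum
    observed time.  Smaller values indicate better-calibrated predictions.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if grid is None:
        grid = np.linspace(0.0, float(time.max()), 100)
    grid = np.asarray(grid, dtype=float)
    G = km_estimator(time, ~event)
    bs = np.array(
        [brier_score(S_matrix, eval_times, time, event, t, G=G) for t in grid]
    )
    span = grid[-1] - grid[0]
    return float(np.trapezoid(bs, grid) / span)


@dataclass
class MetricReport:
    """C-index / IBS pair with the Brier curve behind the integral."""

    c_index_td: float
    ibs: float
    bs_curve: list[tuple[float, float]] = field(default_factory=list)
    eval_grid: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "c_index_td": self.c_index_td,
                "ibs": self.ibs,
                "bs_curve": self.bs_curve,
                "eval_grid": self.eval_grid,
            }
        )


def evaluate_predictions(S_matrix, eval_times, time, event, n_ibs_grid: int = 100) -> MetricReport:
    """Convenience wrapper computing both headline metrics on one cohort."""
    time = np.asarray(time, dtype=float)
    grid = np.linspace(0.0, float(time.max()), n_ibs_grid)
    G = km_estimator(time, 1 - np.asarray(event))
    bs = [brier_score(S_matrix, eval_times, time, event, t, G=G) for t in grid]
    ibs = float(np.trapezoid(bs, grid) / (grid[-1] - grid[0]))
    c = c_index_td(S_matrix, eval_times, time, event)
    return MetricReport(
        c_index_td=c,
        ibs=ibs,
        bs_curve=list(zip(grid.tolist(), map(float, bs))),
        eval_grid=grid.tolist(),
    )
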