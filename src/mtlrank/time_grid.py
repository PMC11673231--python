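"""Follow-up time discretization and survival-curve interpolation.

A :class:`TimeGrid` holds m strictly increasing cut points (with an implicit
tau_0 = 0) produced either on an equidistant grid or at Kaplan-Meier survival
quantiles.  Discrete survival estimates defined at the cuts are interpolated
back to continuous time with constant-density (CDI, linear in S) or
constant-hazard (CHI, piecewise-exponential in S) interpolation.

Intervals are left-open/right-closed, (tau_{k-1}, tau_k]: an event exactly at
a cut belongs to the earlier interval, matching Kaplan-Meier step behavior.
Times beyond tau_m clamp to interval m so a grid fitted on one cohort can be
transferred to another with longer follow-up.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .evaluation import km_estimator

logger = logging.getLogger(__name__)

SCHEMES = ("equidistant", "km_quantiles")
INTERPOLATIONS = ("CDI", "CHI")


@dataclass
class TimeGrid:
    cuts: np.ndarray  # strictly increasing, tau_1 .. tau_m
    scheme: str
    m: int = field(init=False)

    def __post_init__(self) -> None:
        self.cuts = np.asarray(self.cuts, dtype=float)
        if self.cuts.ndim != 1 or len(self.cuts) < 1:
            raise ValueError("cuts must be a 1-d array with at least one cut")
        if np.any(np.diff(self.cuts) <= 0) or self.cuts[0] <= 0:
            raise ValueError("cuts must be strictly increasing and positive")
        self.m = len(self.cuts)

    def to_dict(self) -> dict:
        return {"cuts": self.cuts.tolist(), "scheme": self.scheme}

    @classmethod
    def from_dict(cls, d: dict) -> "TimeGrid":
        return cls(cuts=np.asarray(d["cuts"], dtype=float), scheme=d["scheme"])


def make_grid(time, event, m: int, scheme: str = "km_quantiles") -> TimeGrid:
    """Fit an m-interval grid to observed follow-up times.

    equidistant: cuts at j * max(time) / m for j = 1..m.
    km_quantiles: cuts where the Kaplan-Meier survival estimate first drops
    to or below the equally spaced levels 1 - j/m; duplicate cut times are
    collapsed (m reduced, with a warning).  The last cut is clamped to the
    maximum observed time so the grid always covers the fitting data.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if m < 2:
        raise ValueError("m must be >= 2")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    t_max = float(time.max())
    if scheme == "equidistant":
        cuts = t_max * np.arange(1, m + 1) / m
        return TimeGrid(cuts=cuts, scheme=scheme)

    if not np.any(event):
        raise ValueError("km_quantiles requires at least one event")
    km = km_estimator(time, event)
    levels = 1.0 - np.arange(1, m + 1) / m
    cuts = []
    for lv in levels:
        below = km.times[km.surv <= lv + 1e-12]
        cuts.append(float(below[0]) if len(below) else t_max)
    cuts = np.asarray(cuts)
    cuts[-1] = t_max
    uniq = np.unique(cuts[cuts > 0])
    if len(uniq) < m:
        warnings.warn(
            f"KM-quantile grid collapsed from m={m} to {len(uniq)} distinct cuts",
            stacklevel=2,
        )
    return TimeGrid(cuts=uniq, scheme=scheme)


def assign_interval(t, grid: TimeGrid) -> np.ndarray:
    """Interval index k in 1..m with tau_{k-1} < t <= tau_k; t > tau_m -> m."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    k = np.searchsorted(grid.cuts, t, side="left") + 1
    n_clamped = int(np.sum(k > grid.m))
    if n_clamped:
        logger.info("clamped %d time(s) beyond the last cut to interval m", n_clamped)
        k = np.minimum(k, grid.m)
    return k if k.ndim else int(k)


def interpolate_survival(S_at_cuts, grid: TimeGrid, t, scheme: str = "CDI") -> np.ndarray:
    """Evaluate discrete survival curves at arbitrary times.

    ``S_at_cuts`` is (n, m) with S(tau_0) = 1 implicit; ``t`` may be a scalar
    or a vector of evaluation times; returns shape (n,) or (n, len(t)).

    CDI interpolates S linearly between adjacent cuts (constant event
    density within the interval); CHI raises the interval's survival ratio
    to the elapsed fraction, S(t) = S(tau_{j-1}) * (S(tau_j)/S(tau_{j-1}))^u
    with u the fractional position in the interval (constant hazard).  Both
    are exact at the cut points.  Times beyond tau_m return S(tau_m) with a
    warning.
    """
    if scheme not in INTERPOLATIONS:
        raise ValueError(f"unknown interpolation {scheme!r}; expected one of {INTERPOLATIONS}")
    S = np.atleast_2d(np.asarray(S_at_cuts, dtype=float))
    n, m = S.shape
    if m != grid.m:
        raise ValueError("S_at_cuts width does not match the grid")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr > grid.cuts[-1] + 1e-12):
        warnings.warn("evaluation time(s) beyond the last cut; returning S(tau_m)", stacklevel=2)
    edges = np.concatenate([[0.0], grid.cuts])
    S_full = np.concatenate([np.ones((n, 1)), S], axis=1)
    # interval j such that edges[j-1] < t <= edges[j], clamped to 1..m
    j = np.clip(np.searchsorted(edges, t_arr, side="left"), 1, m)
    lo, hi = edges[j - 1], edges[j]
    u = np.clip((t_arr - lo) / np.where(hi > lo, hi - lo, 1.0), 0.0, 1.0)
    S_lo, S_hi = S_full[:, j - 1], S_full[:, j]
    if scheme == "CDI":
        out = S_lo + (S_hi - S_lo) * u[None, :]
    else:
        eps = 1e-300
        ratio = np.maximum(S_hi, eps) / np.maximum(S_lo, eps)
        out = np.maximum(S_lo, eps) * ratio ** u[None, :]
        out = np.where(S_lo <= eps, 0.0, out)
    if np.isscalar(t) or np.ndim(t) == 0:
        out = out[:, 0]
    return out[0] if np.asarray(S_at_cuts).ndim == 1 else out
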