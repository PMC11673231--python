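"""Quantile-cutoff risk grouping, Kaplan-Meier curves and the log-rank test.

An activity score per subject is split at an empirical quantile into low-
and high-risk groups; the fitted cutoff can then be transferred verbatim to
an external cohort (the group sizes it produces there are reported, since
score distributions shift between cohorts).  By default a HIGHER activity
score means LOWER risk — the combined gene sets this package targets are
dominated by immune-activation programs associated with better survival —
but the direction is a flag, not an assumption baked in.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .evaluation import KMCurve, km_estimator

logger = logging.getLogger(__name__)


@dataclass
class RiskStratification:
    cutoff: float
    low_risk_fraction: float
    labels: np.ndarray  # strings "low" / "high"
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    km_low: KMCurve | None = None
    km_high: KMCurve | None = None


def fit_cutoff(scores: np.ndarray, low_risk_fraction: float = 0.30,
               high_score_low_risk: bool = True) -> float:
    """Cutoff at the empirical quantile giving the requested low-risk share.

    With ``high_score_low_risk`` the cutoff is the (1 - fraction) order-
    statistic quantile (type 1) and subjects with score strictly above it
    are low-risk; with the opposite direction it is the fraction-quantile
    and scores strictly below are low-risk.  Heavy ties at the cutoff can
    shift the realized fraction; the realized group sizes are logged.
    """
    scores = np.asarray(scores, dtype=float)
    if not 0.0 < low_risk_fraction < 1.0:
        raise ValueError("low_risk_fraction must lie in (0, 1)")
    if np.unique(scores).size < 2:
        raise ValueError("all scores equal; no cutoff exists")
    q = 1.0 - low_risk_fraction if high_score_low_risk else low_risk_fraction
    srt = np.sort(scores)
    cutoff = float(srt[max(math.ceil(q * len(scores)) - 1, 0)])
    labels = apply_cutoff(scores, cutoff, high_score_low_risk)
    logger.info(
        "fit_cutoff: %.6g -> %d low / %d high (target fraction %.2f)",
        cutoff, int((labels == "low").sum()), int((labels == "high").sum()), low_risk_fraction,
    )
    return cutoff


def apply_cutoff(scores: np.ndarray, cutoff: float, high_score_low_risk: bool = True) -> np.ndarray:
    """Label subjects with a fixed, externally supplied threshold."""
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    low = scores > cutoff if high_score_low_risk else scores < cutoff
    labels = np.where(low, "low", "high")
    if len(set(labels)) < 2:
        warnings.warn("one risk group is empty; log-rank comparison not possible", stacklevel=2)
    return labels


def log_rank_test(time, event, labels) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("log-rank test needs exactly two non-empty groups")
    if event.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    a = labels == groups[0]
    res = logrank_test(time[a], time[~a], event[a], event[~a])
    return float(res.test_statistic), float(res.p_value)


def km_curves(time, event, labels):
    """Per-group product-limit curves and median survival times.

    Returns ``{group: (KMCurve, median)}``; a single-label input yields one
    curve (fallback for degenerate stratifications).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    labels = np.asarray(labels)
    out = {}
    for g in np.unique(labels):
        mask = labels == g
        curve = km_estimator(time[mask], event[mask])
        out[str(g)] = (curve, curve.median)
    return out


def stratify(
    scores, time, event, subject_ids=None,
    low_risk_fraction: float = 0.30, cutoff: float | None = None,
    high_score_low_risk: bool = True,
) -> RiskStratification:
    """Fit (or apply) a cutoff and run the downstream group comparison."""
    scores = np.asarray(scores, dtype=float)
    if cutoff is None:
        cutoff = fit_cutoff(scores, low_risk_fraction, high_score_low_risk)
    labels = apply_cutoff(scores, cutoff, high_score_low_risk)
    chi2 = p = None
    km_low = km_high = None
    if len(np.unique(labels)) == 2:
        chi2, p = log_rank_test(time, event, labels)
        curves = km_curves(time, event, labels)
        km_low, km_high = curves["low"][0], curves["high"][0]
    return RiskStratification(
        cutoff=float(cutoff),
        low_risk_fraction=low_risk_fraction,
        labels=labels,
        logrank_chi2=chi2,
        logrank_p=p,
        km_low=km_low,
        km_high=km_high,
    )


def plot_km(time, event, labels, path=None, title: str = ""):
    """Kaplan-Meier plot with censoring ticks; saves to ``path`` if given."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for g in np.unique(labels):
        mask = labels == g
        kmf = KaplanMeierFitter(label=f"{g}-risk (n={mask.sum()})")
        kmf.fit(time[mask], event[mask])
        kmf.plot_survival_function(ax=ax, show_censors=True)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
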