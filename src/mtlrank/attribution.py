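"""PatternAttribution: signal-aware feature attributions for survival nets.

Gradients of a network do not point at the signal in the data; they mix the
signal direction with whatever noise directions the weights must cancel.
PatternAttribution instead estimates, per linear unit y = w.x + b, the
direction ``a`` along which the input covaries with the unit's output —
a = cov(x, y) / (w . cov(x, y)) — using the training data, and then runs a
backward pass in which each layer's weights are replaced by w ⊙ a
(elementwise).  For rectified units the expectation is taken over the unit's
active regime (y > 0), the two-regime estimator of the original method; for
saturating activations (tanh/sigmoid) and the linear head the all-example
(linear) estimator is used, which is an approximation documented as such.

The attribution of subject i is the relevance that arrives back at the
input layer when the backward pass is seeded with a one-hot vector at a
chosen output node (one time interval of the survival head).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._mlp import _act_deriv
from .network import FittedModel
from .time_grid import TimeGrid

logger = logging.getLogger(__name__)


@dataclass
class PatternSet:
    """Per-layer signal patterns, same shapes as the layer weight matrices."""

    patterns: list[np.ndarray]
    active_counts: list[np.ndarray]
    flagged: list[np.ndarray]  # units with degenerate/empty regimes


@dataclass
class AttributionMatrix:
    """Per-subject, per-gene contributions for one output node."""

    values: np.ndarray  # (n, p)
    genes: list[str]
    subject_ids: list[str]
    output_node: int  # 1-based interval index
    endpoint_days: float
    root: str = "psi"  # or "phi"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.genes)


def _layer_patterns(x: np.ndarray, y: np.ndarray, W: np.ndarray, positive_regime: bool):
    """Pattern matrix a (same shape as W) for one linear layer.

    x: layer inputs (n, d_in); y: pre-activations (n, d_out).
    """
    d_in, d_out = W.shape
    a = np.zeros_like(W)
    counts = np.zeros(d_out, dtype=int)
    flagged = np.zeros(d_out, dtype=bool)
    for j in range(d_out):
        mask = y[:, j] > 0 if positive_regime else np.ones(len(y), dtype=bool)
        counts[j] = int(mask.sum())
        if counts[j] < 2:
            flagged[j] = True
            continue
        xr, yr = x[mask], y[mask, j]
        cov_xy = (xr * yr[:, None]).mean(axis=0) - xr.mean(axis=0) * yr.mean()
        denom = float(W[:, j] @ cov_xy)
        if abs(denom) < 1e-9:
            flagged[j] = True
            continue
        a[:, j] = cov_xy / denom
    return a, counts, flagged


def fit_patterns(model: FittedModel, X_train: np.ndarray, standardized: bool = False) -> PatternSet:
    """Estimate signal patterns for every linear layer from training data.

    ``X_train`` is the training expression matrix; set ``standardized=True``
    if it has already been transformed with the model's stored statistics.
    """
    mlp = model.mlp
    X = np.asarray(X_train, dtype=float)
    if not standardized:
        X = model._standardize(X)
    _, cache = mlp.forward(X, train=False)
    patterns, counts_l, flagged_l = [], [], []
    rectified = mlp.activation in ("relu", "selu")
    for li in range(mlp.n_hidden_layers):
        a, counts, flagged = _layer_patterns(
            cache["inputs"][li], cache["pre"][li], mlp.weights[li], positive_regime=rectified
        )
        patterns.append(a)
        counts_l.append(counts)
        flagged_l.append(flagged)
        if flagged.any():
            logger.info("layer %d: %d unit(s) with degenerate regime flagged", li, int(flagged.sum()))
    # linear head: all-example estimator
    head_in = cache["inputs"][-1]
    head_out = head_in @ mlp.weights[-1] + mlp.biases[-1]
    a, counts, flagged = _layer_patterns(head_in, head_out, mlp.weights[-1], positive_regime=False)
    patterns.append(a)
    counts_l.append(counts)
    flagged_l.append(flagged)
    return PatternSet(patterns=patterns, active_counts=counts_l, flagged=flagged_l)


def attribute(
    model: FittedModel,
    patterns: PatternSet,
    X: np.ndarray,
    output_node: int,
    standardized: bool = False,
    root: str = "psi",
) -> AttributionMatrix:
    """Backpropagate relevance from one output node to the input genes.

    The backward pass mirrors the gradient computation but with every weight
    matrix replaced by ``W ⊙ a`` and the usual activation gating at the
    subject's own forward pass.  ``root="psi"`` seeds the selected raw head
    unit; ``root="phi"`` seeds the cumulated logit, i.e. all head units at or
    beyond the node (the reverse-cumsum adjoint).
    """
    mlp = model.mlp
    m = mlp.weights[-1].shape[1]
    if not 1 <= output_node <= m:
        raise ValueError(f"output_node must lie in 1..{m}")
    if root not in ("psi", "phi"):
        raise ValueError("root must be 'psi' or 'phi'")
    Xs = np.asarray(X, dtype=float)
    if not standardized:
        Xs = model._standardize(Xs)
    _, cache = mlp.forward(Xs, train=False)
    n = Xs.shape[0]
    seed = np.zeros((n, m))
    if root == "psi":
        seed[:, output_node - 1] = 1.0
    else:
        seed[:, output_node - 1 :] = 1.0
    Wh = np.nan_to_num(mlp.weights[-1] * patterns.patterns[-1])
    rel = seed @ Wh.T
    for li in range(mlp.n_hidden_layers - 1, -1, -1):
        rel = rel * _act_deriv(mlp.activation, cache["pre"][li])
        Wl = np.nan_to_num(mlp.weights[li] * patterns.patterns[li])
        rel = rel @ Wl.T
    rel = np.nan_to_num(rel)
    endpoint = float(model.grid.cuts[output_node - 1]) if model.grid is not None else float("nan")
    return AttributionMatrix(
        values=rel,
        genes=list(model.genes),
        subject_ids=[str(i) for i in range(n)],
        output_node=output_node,
        endpoint_days=endpoint,
        root=root,
    )


def select_endpoint_nodes(grid: TimeGrid, targets_days: list[float]) -> list[int]:
    """Nearest-cut interval index for each requested endpoint (1-based)."""
    nodes = []
    for t in targets_days:
        idx = int(np.argmin(np.abs(grid.cuts - t))) + 1
        if t > grid.cuts[-1]:
            logger.warning("endpoint %s d beyond the last cut %.1f d; using interval m", t, grid.cuts[-1])
        logger.info("endpoint %s d -> interval %d (cut %.1f d)", t, idx, grid.cuts[idx - 1])
        nodes.append(idx)
    if len(set(nodes)) < len(nodes):
        logger.warning("grid too coarse: multiple endpoints map to the same interval")
    return nodes
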