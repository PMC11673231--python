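"""Survival loss functions for discrete-time and proportional-hazards networks.

All losses are pure functions of raw network outputs and ``(interval index,
event, time)`` labels, expressed with NumPy arrays.  The discrete-time family
shares one parameterization: the network emits per-interval scores ``psi``
(n x m); their reverse cumulative sum ``phi`` is treated as the first m logits
of an (m+1)-category softmax whose last, implicit logit is 0 (the category
"survives beyond the last cut").  The event-time probability mass function
(PMF) and the discrete survival function follow from that softmax.

Each ``loss_*`` function has a ``loss_*_grad`` companion returning
``(loss, d loss / d raw-output)`` for use by the trainer; gradients are
analytic and are verified against central differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LOG_FLOOR = 1e-12


@dataclass
class DiscretePrediction:
    """Discrete-time survival prediction for n subjects over m intervals.

    Attributes
    ----------
    psi : raw network outputs, shape (n, m); may be None when constructed
        directly from logits.
    phi : reverse cumulative sums of psi, shape (n, m).
    pmf : probability mass over the m intervals plus the residual category
        "beyond the last cut", shape (n, m + 1); rows sum to 1.
    S_at_cuts : survival probabilities evaluated at the m cut points,
        shape (n, m); row k equals 1 minus the running sum of the pmf row.
    """

    psi: np.ndarray | None
    phi: np.ndarray
    pmf: np.ndarray
    S_at_cuts: np.ndarray


def reverse_cumsum(psi: np.ndarray) -> np.ndarray:
    """phi[:, j] = sum_{k >= j} psi[:, k] (row-wise reverse cumulative sum)."""
    psi = np.asarray(psi, dtype=float)
    return np.cumsum(psi[:, ::-1], axis=1)[:, ::-1]


def pmf_from_phi(phi: np.ndarray, psi: np.ndarray | None = None) -> DiscretePrediction:
    """Softmax the logits (phi_1..phi_m, 0) into a pmf and survival curve.

    The "1 +" in the softmax denominator is realized as an appended zero
    logit; subtracting the row max of the full (m+1)-logit vector makes the
    computation exact under stabilization rather than approximate.
    """
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    n, m = phi.shape
    z = np.concatenate([phi, np.zeros((n, 1))], axis=1)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    pmf = e / e.sum(axis=1, keepdims=True)
    S = 1.0 - np.cumsum(pmf[:, :m], axis=1)
    np.clip(S, 0.0, 1.0, out=S)
    return DiscretePrediction(psi=psi, phi=phi, pmf=pmf, S_at_cuts=S)


def predict_discrete(psi: np.ndarray) -> DiscretePrediction:
    """Full head transform: raw scores -> reverse cumsum -> softmax pmf."""
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    return pmf_from_phi(reverse_cumsum(psi), psi=psi)


def _check_k_idx(k_idx: np.ndarray, m: int) -> np.ndarray:
    k_idx = np.asarray(k_idx, dtype=int)
    if k_idx.min() < 1 or k_idx.max() > m:
        raise ValueError(f"interval indices must lie in 1..{m}")
    return k_idx


def loss_pmf(pred: DiscretePrediction, k_idx: np.ndarray, event: np.ndarray) -> float:
    """Discrete-time negative log-likelihood, mean-reduced over subjects.

    Events contribute -log of their interval's mass, censored subjects -log
    of the survival estimate at their interval's cut; log arguments are
    floored at 1e-12 so saturated predictions yield large finite penalties.
    """
    n, m = pred.S_at_cuts.shape
    k_idx = _check_k_idx(k_idx, m)
    event = np.asarray(event, dtype=float)
    rows = np.arange(n)
    sigma_k = pred.pmf[rows, k_idx - 1]
    S_k = pred.S_at_cuts[rows, k_idx - 1]
    ll = event * np.log(np.maximum(sigma_k, LOG_FLOOR)) + (1.0 - event) * np.log(
        np.maximum(S_k, LOG_FLOOR)
    )
    return float(-np.mean(ll))


def _loss_pmf_grad_phi(
    pred: DiscretePrediction, k_idx: np.ndarray, event: np.ndarray
) -> tuple[float, np.ndarray]:
    """(loss, d loss/d phi) for the PMF likelihood."""
    n, m = pred.S_at_cuts.shape
    k_idx = _check_k_idx(k_idx, m)
    event = np.asarray(event, dtype=float)
    rows = np.arange(n)
    p = pred.pmf[:, :m]
    F = np.cumsum(pred.pmf[:, :m], axis=1)
    S_k = np.maximum(pred.S_at_cuts[rows, k_idx - 1], LOG_FLOOR)
    F_k = F[rows, k_idx - 1]

    # event subjects: d(-log sigma_k)/d phi_l = p_l - 1[l == k]
    g_event = p.copy()
    g_event[rows, k_idx - 1] -= 1.0
    # censored subjects: d(-log S_k)/d phi_l = p_l (1[l <= k] - F_k) / S_k
    le_mask = np.arange(1, m + 1)[None, :] <= k_idx[:, None]
    g_cens = p * (le_mask - F_k[:, None]) / S_k[:, None]

    grad = (event[:, None] * g_event + (1.0 - event)[:, None] * g_cens) / n
    return loss_pmf(pred, k_idx, event), grad


def loss_nmtlr(psi: np.ndarray, k_idx: np.ndarray, event: np.ndarray) -> float:
    """N-MTLR likelihood: the PMF loss on the reverse-cumulated outputs."""
    return loss_pmf(predict_discrete(psi), k_idx, event)


def _comparable_pairs(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Boolean (i, j) mask: d_i = 1 and t_i < t_j (ties in time excluded)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    return (np.asarray(event, dtype=bool)[:, None]) & (time[:, None] < time[None, :])


def loss_rank(
    pred: DiscretePrediction,
    k_idx: np.ndarray,
    event: np.ndarray,
    time: np.ndarray,
    beta: float,
    reduction: str = "mean",
) -> float:
    """Pairwise ranking penalty on discrete survival estimates.

    Over ordered pairs (i, j) with ``d_i = 1`` and ``t_i < t_j`` the term
    ``exp[(S(k(t_i)|X_i) - S(k(t_i)|X_j)) / beta]`` is accumulated: it
    penalizes giving the earlier-failing subject i a *higher* survival
    estimate, at i's own interval, than the longer-surviving subject j.
    Reduced as the mean over comparable pairs (``reduction="sum"`` gives the
    bare sum); 0 when no pair is comparable.
    """
    loss, _ = _loss_rank_grad_S(pred, k_idx, event, time, beta, reduction)
    return loss


def _loss_rank_grad_S(
    pred: DiscretePrediction,
    k_idx: np.ndarray,
    event: np.ndarray,
    time: np.ndarray,
    beta: float,
    reduction: str = "mean",
) -> tuple[float, np.ndarray]:
    """(loss, d loss/d S_at_cuts) for the ranking penalty."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if reduction not in ("mean", "sum"):
        raise ValueError("reduction must be 'mean' or 'sum'")
    n, m = pred.S_at_cuts.shape
    k_idx = _check_k_idx(k_idx, m)
    pairs = _comparable_pairs(time, event)
    dS = np.zeros_like(pred.S_at_cuts)
    n_pairs = int(pairs.sum())
    if n_pairs == 0:
        return 0.0, dS
    # Sk[i, j] = S(k(t_i) | X_j): subject j's survival at i's interval.
    Sk = pred.S_at_cuts[:, k_idx - 1].T
    terms = np.exp((np.diag(Sk)[:, None] - Sk) / beta) * pairs
    denom = n_pairs if reduction == "mean" else 1
    loss = float(terms.sum() / denom)
    w = terms / (denom * beta)
    np.add.at(dS, (np.arange(n), k_idx - 1), w.sum(axis=1))
    np.add.at(dS.T, (k_idx - 1, slice(None)), -w)
    return loss, dS


def _grad_S_to_phi(pred: DiscretePrediction, dS: np.ndarray) -> np.ndarray:
    """Chain a gradient w.r.t. S_at_cuts back to the logits phi.

    Uses dS_k/dphi_l = -sigma_l (1[l <= k] - F_k) with F the pmf running sum.
    """
    m = dS.shape[1]
    p = pred.pmf[:, :m]
    F = np.cumsum(pred.pmf[:, :m], axis=1)
    tail = np.cumsum(dS[:, ::-1], axis=1)[:, ::-1]  # sum_{k >= l} dS_k
    dot = (dS * F).sum(axis=1, keepdims=True)
    return -p * (tail - dot)


def loss_deephit(
    pred: DiscretePrediction,
    k_idx: np.ndarray,
    event: np.ndarray,
    time: np.ndarray,
    alpha: float,
    beta: float,
) -> float:
    """Composite alpha * PMF likelihood + (1 - alpha) * ranking penalty."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * loss_pmf(pred, k_idx, event) + (1.0 - alpha) * loss_rank(
        pred, k_idx, event, time, beta
    )


def loss_nmtlr_rank(
    psi: np.ndarray,
    k_idx: np.ndarray,
    event: np.ndarray,
    time: np.ndarray,
    alpha: float,
    beta: float,
) -> float:
    """Composite likelihood + ranking loss on the cumulated head.

    alpha * loss_nmtlr + (1 - alpha) * loss_rank, both evaluated on the pmf
    derived from the reverse cumulative sum of ``psi``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    pred = predict_discrete(psi)
    return alpha * loss_pmf(pred, k_idx, event) + (1.0 - alpha) * loss_rank(
        pred, k_idx, event, time, beta
    )


def discrete_loss_grad(
    psi: np.ndarray,
    k_idx: np.ndarray,
    event: np.ndarray,
    time: np.ndarray,
    alpha: float,
    beta: float,
    use_cumsum: bool = True,
) -> tuple[float, np.ndarray]:
    """Composite discrete-time loss and its gradient w.r.t. raw outputs.

    ``use_cumsum=True`` gives the cumulated-head (N-MTLR-style) family,
    ``False`` the direct-pmf (DeepHit-style) family where ``psi`` itself is
    used as the logits.  alpha = 1 reduces to the pure likelihood, alpha = 0
    to the pure ranking penalty.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    pred = predict_discrete(psi) if use_cumsum else pmf_from_phi(psi, psi=psi)

    l_lik, g_lik_phi = _loss_pmf_grad_phi(pred, k_idx, event)
    if alpha < 1.0:
        l_rank, dS = _loss_rank_grad_S(pred, k_idx, event, time, beta)
        g_rank_phi = _grad_S_to_phi(pred, dS)
    else:
        l_rank, g_rank_phi = 0.0, 0.0
    g_phi = alpha * g_lik_phi + (1.0 - alpha) * g_rank_phi
    loss = alpha * l_lik + (1.0 - alpha) * l_rank
    if use_cumsum:
        # phi_j = sum_{k >= j} psi_k  =>  d/d psi_k = sum_{j <= k} d/d phi_j
        g_psi = np.cumsum(g_phi, axis=1)
    else:
        g_psi = g_phi
    return float(loss), g_psi


def loss_cox(theta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox negative partial log-likelihood, Breslow ties, mean over events."""
    loss, _ = loss_cox_grad(theta, time, event)
    return loss


def loss_cox_grad(
    theta: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, np.ndarray]:
    """(loss, d loss/d theta) for the Cox partial likelihood.

    Risk set R_j = {i : t_i >= t_j}; tied event times share the full risk
    set (Breslow).  Loss is the mean over events of
    -[theta_j - log sum_{R_j} exp theta_i].
    """
    theta = np.asarray(theta, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event, dtype=bool).ravel()
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("Cox partial likelihood undefined with no events")
    order = np.argsort(-time, kind="stable")  # descending time
    th, tt, ev = theta[order], time[order], event[order]
    c = th.max()
    cum = np.cumsum(np.exp(th - c))
    # tied times share the risk-set sum of the last subject at that time
    last_of_tie = np.searchsorted(-tt, -tt, side="right") - 1
    log_risk = np.log(cum[last_of_tie]) + c
    ll = (th - log_risk)[ev].sum()
    loss = float(-ll / n_events)

    # gradient: d(-ll)/d theta_i = -(d_i - e^{theta_i} * sum over events j
    # with t_j <= t_i of 1 / riskset_sum_j), mean-reduced
    inv = np.where(ev, 1.0 / cum[last_of_tie], 0.0)
    # events with t_j <= t_i are those at or after position i in desc order
    inv_tail = np.cumsum(inv[::-1])[::-1]
    first_of_tie = np.searchsorted(-tt, -tt, side="left")
    g_sorted = -(ev.astype(float) - np.exp(th - c) * inv_tail[first_of_tie]) / n_events
    grad = np.empty_like(g_sorted)
    grad[order] = g_sorted
    return loss, grad
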