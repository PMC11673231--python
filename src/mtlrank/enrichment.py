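"""Per-patient gene-set enrichment and single-sample activity scoring.

Two rank-based statistics live here.  Preranked GSEA walks a gene list
sorted by per-patient attribution scores and measures whether a set's
members pile up at either extreme (weighted Kolmogorov-Smirnov running sum;
significance by gene-label permutation, Benjamini-Hochberg corrected across
sets within each patient).  The GSVA-style activity score summarizes a
combined gene set per sample from kernel-smoothed expression ECDFs, giving a
single number usable for risk stratification without any model in the loop.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .attribution import AttributionMatrix
from .cohort_io import GeneSetCollection

logger = logging.getLogger(__name__)


def _es_from_hits(weights: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Enrichment scores for one or many hit masks over a sorted list.

    ``weights``: |score|^w per ranked position (length N).
    ``hits``: boolean (B, N); each row one hit configuration.
    Hit positions increment the running sum proportionally to their weight,
    misses decrement by 1/(N - N_h); the ES is the running sum's maximal
    deviation from zero, signed.
    """
    hits = np.atleast_2d(hits)
    B, N = hits.shape
    n_hit = hits.sum(axis=1)
    if np.any(n_hit == 0) or np.any(n_hit == N):
        raise ValueError("each hit mask must be a non-empty strict subset of the ranking")
    hit_w = np.where(hits, weights[None, :], 0.0)
    sum_w = hit_w.sum(axis=1, keepdims=True)
    inc = np.where(sum_w > 0, hit_w / np.where(sum_w > 0, sum_w, 1.0),
                   hits / n_hit[:, None])  # all-zero hit scores: uniform steps
    dec = np.where(hits, 0.0, 1.0 / (N - n_hit)[:, None])
    run = np.cumsum(inc - dec, axis=1)
    idx = np.argmax(np.abs(run), axis=1)
    return run[np.arange(B), idx]


def gsea_preranked(
    genes: list[str],
    scores: np.ndarray,
    gene_set: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> tuple[float, float]:
    """Weighted-KS enrichment score and permutation p-value for one set.

    ``genes``/``scores`` are the ranked list (descending scores expected; the
    function sorts defensively).  The null permutes gene labels: the set's
    size is re-drawn uniformly over ranked positions ``n_perm`` times.  The
    p-value is one-sided on the sign of the observed ES, floored at
    1/(n_perm + 1).
    """
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    genes_sorted = [genes[i] for i in order]
    w = np.abs(scores[order]) ** weight
    members = {g.upper() for g in gene_set}
    hits = np.array([g.upper() in members for g in genes_sorted])
    if not hits.any():
        raise ValueError("gene set does not overlap the ranking")
    if hits.all():
        raise ValueError("gene set covers every ranked gene; miss decrement undefined")
    es = float(_es_from_hits(w, hits[None, :])[0])
    null = _null_es(w, int(hits.sum()), n_perm, np.random.default_rng(seed))
    p = _perm_p(es, null, n_perm)
    return es, p


def _null_es(weights: np.ndarray, n_hit: int, n_perm: int, rng) -> np.ndarray:
    N = len(weights)
    u = rng.random((n_perm, N))
    idx = np.argpartition(u, n_hit - 1, axis=1)[:, :n_hit]
    hits = np.zeros((n_perm, N), dtype=bool)
    np.put_along_axis(hits, idx, True, axis=1)
    return _es_from_hits(weights, hits)


def _perm_p(es: float, null: np.ndarray, n_perm: int) -> float:
    same_sign = null >= 0 if es >= 0 else null <= 0
    n_sign = int(same_sign.sum())
    if n_sign == 0:
        return 1.0 / (n_perm + 1)
    tail = int((np.abs(null[same_sign]) >= abs(es)).sum())
    return max(tail / n_sign, 1.0 / (n_perm + 1))


@dataclass
class EnrichmentResult:
    """Long-format per (patient, set) table plus the cohort frequency summary."""

    table: pd.DataFrame  # columns: patient, gene_set, ES, p_value, p_adjusted, leading_edge_size
    frequency: pd.Series  # per set: fraction of patients significantly enriched
    alpha: float


def enrich_cohort(
    attributions: AttributionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    use_absolute: bool = False,
    positive_only: bool = False,
) -> EnrichmentResult:
    """Preranked GSEA for every patient and every gene set.

    Genes are ranked per patient by attribution (descending; signed by
    default, absolute with ``use_absolute``).  P-values are BH-corrected
    across sets within each patient; the frequency summary is the fraction
    of patients with adjusted p < alpha per set (optionally counting
    positive-ES enrichments only).  Permutation nulls are shared across sets
    of equal size within a patient.
    """
    genes = [g.upper() for g in attributions.genes]
    vals = attributions.values
    usable = {}
    for name, members in sets.sets.items():
        ov = [g for g in members if g in set(genes)]
        if not ov or len(ov) >= len(genes):
            warnings.warn(f"gene set {name!r} skipped (overlap {len(ov)}/{len(genes)})", stacklevel=2)
            continue
        usable[name] = set(ov)
    rows = []
    rng = np.random.default_rng(seed)
    for pi, patient in enumerate(attributions.subject_ids):
        scores = np.abs(vals[pi]) if use_absolute else vals[pi]
        order = np.argsort(-scores, kind="stable")
        ranked = [genes[i] for i in order]
        w = np.abs(scores[order])
        nulls: dict[int, np.ndarray] = {}
        pvals, ess, les = [], [], []
        for name, members in usable.items():
            hits = np.array([g in members for g in ranked])
            es = float(_es_from_hits(w, hits[None, :])[0])
            nh = int(hits.sum())
            if nh not in nulls:
                nulls[nh] = _null_es(w, nh, n_perm, rng)
            p = _perm_p(es, nulls[nh], n_perm)
            run_peak = int(np.argmax(np.cumsum(np.where(hits, 1.0, 0.0)))) if es >= 0 else 0
            ess.append(es)
            pvals.append(p)
            les.append(int(hits[: run_peak + 1].sum()) if es >= 0 else int(hits.sum()))
        p_adj = multipletests(pvals, method="fdr_bh")[1] if pvals else []
        for (name, es, p, pa, le) in zip(usable, ess, pvals, p_adj, les):
            rows.append(
                {
                    "patient": patient,
                    "gene_set": name,
                    "ES": es,
                    "p_value": p,
                    "p_adjusted": pa,
                    "leading_edge_size": le,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no usable gene sets")
    sig = table["p_adjusted"] < alpha
    if positive_only:
        sig &= table["ES"] > 0
    n_patients = len(attributions.subject_ids)
    freq = (
        table[sig].groupby("gene_set").size().reindex(list(usable), fill_value=0) / n_patients
    )
    return EnrichmentResult(table=table, frequency=freq.sort_values(ascending=False), alpha=alpha)


def combine_sets(
    sets: GeneSetCollection,
    names: list[str] | None = None,
    min_frequency: float | None = None,
    freq_table: pd.Series | None = None,
) -> list[str]:
    """Union of member genes over named sets or sets above a frequency cut."""
    if names is None:
        if freq_table is None or min_frequency is None:
            raise ValueError("supply names, or freq_table with min_frequency")
        names = list(freq_table[freq_table > min_frequency].index)
        logger.info("combine_sets: %d set(s) above frequency %.3f", len(names), min_frequency)
    if not names:
        raise ValueError("no gene sets selected to combine")
    combined: dict[str, None] = {}
    for name in names:
        for g in sets.sets[name]:
            combined.setdefault(g.upper())
    return list(combined)


def gsva_score(
    X: np.ndarray,
    genes: list[str],
    combined_set: list[str],
    tau: float = 1.0,
) -> np.ndarray:
    """Single-sample activity score of one gene set (GSVA algorithm).

    ``X`` is samples x genes on the log scale, *not* standardized to a
    training set — the score is relative to the scoring cohort itself.
    Per gene, a Gaussian-kernel-smoothed ECDF across samples yields an
    expression-level statistic; per sample the statistics are ranked and
    symmetrized around the middle rank; a KS-like random walk down the
    sample's ranked gene list (hits = set members, weighted by the rank
    statistic^tau) gives score = max positive deviation + max negative
    deviation (their signed sum, the max-deviation-difference variant).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("GSVA requires at least 2 samples (ECDF across samples)")
    members = {g.upper() for g in combined_set}
    hit_cols = np.array([g.upper() in members for g in genes])
    if not hit_cols.any():
        raise ValueError("combined set does not overlap the gene list")

    # kernel-smoothed ECDF per gene across samples (bandwidth sd/4)
    sd = X.std(axis=0, ddof=1)
    h = np.where(sd > 0, sd / 4.0, 1.0)
    kcdf = np.empty_like(X)  # (n samples, p genes); per-gene loop bounds memory
    for g in range(p):
        kcdf[:, g] = norm.cdf((X[:, g][:, None] - X[:, g][None, :]) / h[g]).mean(axis=1)

    # per-sample ranks of the statistic, symmetrized: |p/2 - r|
    order = np.argsort(-kcdf, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(1, p + 1)[None, :]
    stat = np.abs(p / 2.0 - ranks).astype(float)

    scores = np.empty(n)
    n_hit = int(hit_cols.sum())
    for i in range(n):
        ord_i = order[i]
        hits = hit_cols[ord_i]
        w = stat[i, ord_i] ** tau
        sw = w[hits].sum()
        inc = np.where(hits, w / (sw if sw > 0 else 1.0), 0.0)
        dec = np.where(hits, 0.0, 1.0 / (p - n_hit))
        run = np.cumsum(inc - dec)
        scores[i] = run.max() + min(run.min(), 0.0)
    return scores
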