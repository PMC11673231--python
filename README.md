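# mtlrank

Discrete-time deep survival analysis for transcriptomic cohorts, built
around a composite likelihood + ranking loss, with an interpretation arm
that turns a trained network into pathway-level biology: feature
attributions → per-patient gene-set enrichment → a single-sample activity
score → quantile risk stratification.

## Who this is for

Researchers fitting survival models to bulk (or pseudo-bulk) gene-expression
matrices — a few hundred patients, thousands of genes, heavy right-censoring
— who want both a calibrated survival curve per patient and an answer to
"which biological programs is the network actually using?".

## The model

Each patient is a triplet (Xᵢ, tᵢ, dᵢ): expression vector, observed time,
and event indicator (1 = death observed, 0 = right-censored). Follow-up is
cut into m intervals (equidistant or at Kaplan–Meier survival quantiles). A
fully connected network maps X to per-interval scores ψ(X) ∈ ℝᵐ; a fixed
reverse-cumulative-sum transform gives logits φⱼ(X) = Σ_{k≥j} ψₖ(X), so the
estimate at any interval depends on the estimates at all later intervals
(the multi-task logistic regression construction). A softmax over
(φ₁…φₘ, 0) yields the event-time probability mass σₖ and the discrete
survival function Ŝ(k|X) = 1 − Σ_{j≤k} σⱼ.

Training minimizes the composite loss

    L = α · L_lik + (1 − α) · L_rank

where `L_lik` is the discrete-time negative log-likelihood
(−1/n Σ dᵢ log σ_{k(tᵢ)} + (1−dᵢ) log Ŝ(k(tᵢ)|Xᵢ)) and `L_rank` penalizes,
for every comparable pair (dᵢ=1, tᵢ<tⱼ),
exp[(Ŝ(k(tᵢ)|Xᵢ) − Ŝ(k(tᵢ)|Xⱼ))/β]: a patient who dies earlier should not
carry the higher survival estimate at their own event time. Setting α=1
recovers the pure likelihood model; the direct-softmax variants (with and
without the ranking term) and a Cox partial-likelihood head are included as
baselines. Evaluation uses the time-dependent (Antolini) concordance index
and the IPCW integrated Brier score; discrete curves are interpolated back
to continuous time by constant-density (linear) or constant-hazard
(piecewise-exponential) interpolation.

For interpretation, PatternAttribution estimates per-unit signal patterns
a = cov(x, y)/(w·cov(x, y)) from training data and backpropagates a chosen
output node through weights w⊙a, giving per-patient, per-gene attributions.
Genes ranked by attribution feed per-patient preranked GSEA (weighted
Kolmogorov–Smirnov statistic, gene-label permutation null,
Benjamini–Hochberg across sets within patient); the most frequently
enriched sets are merged, scored per sample with the GSVA algorithm, and
the score split at an empirical quantile defines low/high-risk groups
compared by Kaplan–Meier curves and the log-rank test. A fitted cutoff can
be transferred verbatim to an external cohort.

## Worked example

```python
import numpy as np
import mtlrank as mt
from mtlrank.simulate import SimulationConfig, simulate_cohort, decoy_gene_sets

# synthetic cohort: 200 genes, one 25-gene module driving a Weibull hazard,
# ~62% censoring (a realistic ovarian-cancer overall-survival regime)
cohort, membership, _, _ = simulate_cohort(SimulationConfig(n=600, seed=11))

rng = np.random.default_rng(7)
idx = rng.permutation(400)
tr, val = cohort.subset(idx[100:]), cohort.subset(idx[:100])
te = cohort.subset(np.arange(400, 600))

model = mt.train(tr, mt.HyperParams(epochs=512, width=32, seed=7),
                 "nmtlr_rank", val=val)
report = mt.evaluate_model(model, te)
print(f"test C-index = {report.c_index_td:.3f}, IBS = {report.ibs:.3f}")
```

prints

```
test C-index = 0.704, IBS = 0.166
```

a clear gain over chance concordance (0.5) and over the Kaplan–Meier
marginal predictor's IBS of 0.193 on the same test split. Continuing into
the interpretation arm:

```python
patterns = mt.fit_patterns(model, tr.X)
node = mt.select_endpoint_nodes(model.grid, [1919.0])[0]     # ~5-year node
att = mt.attribute(model, patterns, tr.X[:60], node)
sets = decoy_gene_sets(cohort.genes, membership, n_decoys=15, seed=5)
res = mt.enrich_cohort(att, sets, n_perm=200, seed=2)
print(res.frequency.head(3))

scores = mt.gsva_score(te.X, te.genes, mt.combine_sets(sets, names=["RISK_MODULE"]))
strat = mt.stratify(scores, te.time, te.event, high_score_low_risk=False)
print(f"log-rank p = {strat.logrank_p:.2e}")
```

```
RISK_MODULE    0.417
DECOY_10       0.383
DECOY_12       0.033
log-rank p = 4.25e-08
```

The planted module is the most frequently enriched set across patients, and
the activity-score split separates survival at the 30%/70% quantile cutoff.

## Command line

`mtlrank` exposes `simulate`, `train`, `cv`, `tune`, `attribute`, `enrich`,
`score`, `stratify` and an all-in-one `run --config config.yaml` that writes
every stage artifact plus a manifest (config snapshot, seeds, input hashes,
wall times). All tabular outputs are TSV; the model artifact is a directory
of JSON files carrying weights, the time grid, the gene list and the
standardization statistics.

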