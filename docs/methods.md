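# Methods

This note records the modelling choices, numerical conventions and known
limitations behind `mtlrank`, at the level of detail a user would need to
judge what a result does and does not show.

## Survival model

Follow-up is discretized into m intervals (τ₀ = 0 < τ₁ < … < τₘ), with
intervals left-open/right-closed: an event exactly at a cut belongs to the
earlier interval, matching Kaplan–Meier step behaviour. Two discretization
schemes are offered. *Equidistant* places cuts at j·max(t)/m. *KM quantiles*
places cut j where the Kaplan–Meier survival estimate of the fitting data
first drops to 1 − j/m; under heavy censoring the lower levels are never
reached and duplicate cuts collapse (m is reduced with a warning) — with a
~60% censored cohort and m = 10, typically 6–8 usable cuts remain. The last
cut is clamped to the maximum observed fitting time, and times beyond the
grid map to interval m, so a grid fitted on one cohort transfers to another
with longer follow-up.

The network is a fully connected trunk (`n_layers` × `width`, one of
relu/selu/tanh/sigmoid, inverted dropout) with a linear head of width m
emitting raw scores ψ. The reverse cumulative sum φⱼ = Σ_{k≥j} ψₖ is a fixed
transform, not a learned layer. The softmax denominator's "1 +" term is
realized as an appended zero logit — an explicit (m+1)-th category "survives
past τₘ" — which makes the numerically stabilized computation (subtracting
the row max of the full logit vector) exact rather than approximate.

The published form of this softmax carries a leading minus sign that would
make the probabilities negative; it is treated as a typographical slip and
the standard softmax is used.

### Losses

All losses are mean-reduced. The discrete likelihood floors its log
arguments at 1e-12, so a saturated prediction yields a large finite penalty
instead of −∞. The ranking term sums exp[(Ŝ(k(tᵢ)|Xᵢ) − Ŝ(k(tᵢ)|Xⱼ))/β]
over ordered pairs with dᵢ = 1 and tᵢ < tⱼ (ties in raw time excluded,
comparability on raw times rather than interval indices) and is reduced as
the *mean* over comparable pairs so its scale is batch-size invariant; the
bare sum is available as an option. Both survival values are evaluated at
the earlier subject's interval. The Cox head uses Breslow's approximation
for tied event times and a Breslow baseline hazard for survival-curve
prediction.

Gradients of every loss with respect to the raw head outputs are analytic
(softmax/cumulative-sum adjoints written out by hand) and are verified
against central differences in the test suite. Training is Adam in float64
on the CPU with L2 weight decay added to the raw gradient (the convention
of mainstream deep-learning optimizers, where decay up to 0.9 is meaningful
because it multiplies the learning rate). Fixed seeds give bit-identical
loss traces; this CPU determinism is the supported reproducibility
contract.

### Training protocol

Defaults: m = 10, epochs = 512, full-batch below 1024 subjects, and — when
a validation cohort is passed — early stopping on the validation loss with
patience 16, restoring the best weights. Early stopping is not cosmetic
here: with p ≈ 200 genes and a few hundred subjects the network can drive
the training loss toward zero while test concordance decays, and the
validation-monitored fit is what the recovery results quote.
Standardization statistics (zero-mean/unit-variance per gene) are always
computed on training subjects only; zero-variance genes are kept as
all-zero columns rather than dropped so gene indices stay aligned with
attribution outputs. When auxiliary cohorts are pooled into training, the
gene lists are inner-joined, the time grid is fitted on the pooled training
times, and standardization is pooled by default with a per-cohort switch.

Hyperparameter search samples the box n_layers 1–8, width 8–2048
(log-uniform), learning rate 1e-5–0.1 (log-uniform), weight decay 0–0.9,
dropout 0–0.6, four activations, two discretization and two interpolation
schemes, α ∈ [0,1], β ∈ [0.1,100]. The sampler is plain random search; each
trial trains with early stopping and is scored on the validation
time-dependent C-index (switchable to IBS). Every trial is logged with its
parameters, metrics and seed. Repeated cross-validation re-splits each
outer 80% training fold 75/25 into fit/validation for early stopping and
reports per-fold, per-repeat metrics on the untouched test fold.

## Evaluation

The time-dependent concordance index follows Antolini: a pair (i, j) is
comparable when tᵢ < tⱼ with dᵢ = 1, or tᵢ = tⱼ with dᵢ = 1 and dⱼ = 0; it
is concordant when Ŝᵢ(tᵢ) < Ŝⱼ(tᵢ), with ties in the predicted value
scoring ½. Predicted curves are linearly interpolated on the evaluation
grid at each subject's own time. The Brier score at t weights failed
subjects by 1/G(tᵢ⁻) and still-at-risk subjects by 1/G(t), with G the
Kaplan–Meier estimate of the censoring distribution (censorings as
"events"); weights where G ≈ 0 are capped at n (with a warning) rather than
allowed to diverge. The integrated score is a trapezoidal integral over 100
equispaced points from 0 to the maximum observed time, normalized by the
span; the integration window is recorded in every metric report because the
IBS is window-dependent.

## Interpretation arm

PatternAttribution estimates, per linear unit y = w·x + b, the signal
pattern a = (E[x⊙y] − E[x]E[y]) / (w·(E[x⊙y] − E[x]E[y])), with the
expectation over the unit's positive regime (y > 0) for rectified
activations (relu, and selu as an approximation) and over all examples for
saturating activations and the linear head. Units with fewer than two
in-regime examples or a denominator below 1e-9 get a zero pattern and a
flag — they contribute nothing rather than NaN, keeping matrix shapes
stable. Attribution is a backward pass from a one-hot seed at the selected
raw head unit (ψ-rooting, the default, since patterns are estimated per
linear layer) or at the cumulated logit (φ-rooting, seeding all head units
at or beyond the node); the rooting convention is recorded in the output
metadata. Endpoint nodes are chosen as the grid cut nearest the requested
time in days (e.g. 372 and 1919 days for 1- and 5-year endpoints); on a
coarse grid both endpoints can map to one node, which is warned about.

Per-patient preranked GSEA ranks genes by signed attribution (descending;
absolute-value ranking is a flag) and uses the weighted Kolmogorov–Smirnov
running sum with weight exponent 1. The permutation null redraws the set's
positions uniformly among the ranked genes; nulls are shared across sets of
equal size within a patient, which is what makes 50-set × hundreds-of-
patients runs tractable. The p-value is the same-sign tail fraction,
floored at 1/(n_perm + 1); Benjamini–Hochberg correction is applied across
sets within each patient (a cohort-wide option exists), and the
cohort-level summary is the fraction of patients with adjusted p < 0.05 per
set. Whether only positive-ES enrichments count toward that frequency is a
flag (default: either sign).

The activity score follows the GSVA algorithm: per gene, a Gaussian-kernel
smoothed ECDF across samples (bandwidth sd/4); per sample, genes ranked by
that statistic and the rank symmetrized as |p/2 − r|; a KS-like random walk
over the ranked list with hits weighted by the rank statistic; score = max
positive deviation + min negative deviation (the max-deviation-difference
variant). The score is relative to the scoring cohort itself — it is
deliberately *not* standardized to the training set, which is what makes a
fixed cutoff transferable across cohorts in score space.

Stratification uses the type-1 (order-statistic) empirical quantile: with a
low-risk fraction of 0.30 and higher-score-means-lower-risk (the default
direction, exposed as a flag because either direction can be correct for a
given signature), the cutoff is the 70th-percentile order statistic and
scores strictly above it are low-risk. Heavy ties at the cutoff can shift
the realized fraction; realized group sizes are always logged, and applying
a transferred cutoff reports the (possibly very unbalanced) group sizes it
produces. The log-rank test and per-group Kaplan–Meier curves come from
lifelines.

## Synthetic cohorts

The generator plants correlated gene modules whose latent activities drive
a Weibull proportional-hazards event process. Member genes load on a
standard-normal factor with loading √ρ, giving exact pairwise correlation ρ
within the module; background genes are independent noise; the matrix is
placed on a plausible log2(count+1) scale (location 5, scale 2). Event
times are T = scale·E^{1/shape}·exp(−η/shape) with E ~ Exp(1) and η the
effect-weighted sum of factors. Censoring is uniform on (0, c_max) with
c_max bisected until the realized censoring fraction matches the target
(tolerance 0.03, or 1/n for tiny cohorts, since realized fractions move in
steps of 1/n).

Defaults — 200 genes, one 25-gene module with effect 1.0 and correlation
0.6, Weibull scale 1800 days / shape 1.5, censoring target 0.62 — represent
a bulk ovarian-carcinoma overall-survival regime: follow-up on a scale of
years and roughly three of five subjects censored. The benchmark suite adds
a null cohort (no signal), a two-cohort transfer pair sharing the module
but differing in baseline hazard, and a 12-subject "tiny external" cohort
for the small-validation-cohort regime.

What the generator does *not* emulate: count-level noise (expression is
simulated directly on the log scale), batch effects, censoring that depends
on covariates (the IPCW metrics assume independent censoring, and the
generator honours that assumption rather than stress-testing it), and the
15k-gene dimensionality of real matrices. Passing recovery tests therefore
demonstrates the machinery end-to-end under a favourable signal-to-noise
regime, not clinical-grade performance on real cohorts.

## Problem sizes used in tests

The recovery experiments train on 300 subjects with a 100-subject
validation split and test on 200 (the 400/200 design at effect 1.0), over
five seeds; attribution-based enrichment uses 60 patients, 15 decoy sets
and 200 permutations; the log-rank calibration uses 2000 label permutations
at n = 200. These sizes were chosen so the whole suite exercises every
stage at statistically meaningful scale while remaining a routine developer
run (a few minutes end to end on one CPU core).

## Known limitations

- Single event type only; no competing-risks extension of the ranking loss.
- The ranking loss evaluates both subjects at the earlier subject's
  interval, as specified for the discrete survival estimate; the original
  cumulative-incidence formulation of the ranking idea is not offered.
- Random search stands in for model-based Bayesian optimization of
  hyperparameters; with a few dozen trials on the box the difference is
  modest, but a TPE-style sampler would be a natural extension.
- PatternAttribution's two-regime estimator is exact for ReLU; its use for
  SELU and the all-example estimator for saturating activations are
  approximations, documented per run in the output metadata.
- GSVA scores depend on the composition of the scoring cohort (the ECDF is
  cross-sample); transferring a cutoff assumes the cohorts' score
  distributions are comparable, which the small-cohort warning surfaces but
  cannot fix.
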