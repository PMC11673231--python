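"""Construction, training, cross-validation and tuning of survival networks.

The network is a fully connected trunk whose linear head emits one raw score
per time interval; a fixed (non-learned) reverse-cumulative-sum transform
turns those scores into the logits of the discrete-time likelihood.  Five
losses are supported: the composite likelihood+ranking loss that is the
package's centrepiece (``nmtlr_rank``), its pure-likelihood reduction
(``nmtlr``), the direct-pmf variants (``pmf``, ``deephit``) and a Cox
partial-likelihood head (``cox``).

Training is Adam on the CPU in float64; with a fixed seed the loss trace is
bit-reproducible.  A fitted model always travels with its time grid and the
training-set standardization statistics, so predictions on a new cohort are
a single call.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._mlp import MLP, Adam
from .cohort_io import SurvivalCohort, standardize, stratified_kfold
from .evaluation import evaluate_predictions
from .losses import discrete_loss_grad, loss_cox_grad, predict_discrete
from .time_grid import TimeGrid, assign_interval, interpolate_survival, make_grid

LOSSES = ("nmtlr_rank", "nmtlr", "deephit", "pmf", "cox")

# printed hyperparameter search box
_BOX = {
    "n_layers": (1, 8),
    "width": (8, 2048),
    "learning_rate": (1e-5, 0.1),
    "weight_decay": (0.0, 0.9),
    "dropout": (0.0, 0.6),
    "alpha": (0.0, 1.0),
    "beta": (0.1, 100.0),
}
_ACTIVATIONS = ("relu", "selu", "tanh", "sigmoid")


@dataclass
class HyperParams:
    """Architecture and optimization settings, bounded by the search box."""

    n_layers: int = 1
    width: int = 64
    learning_rate: float = 0.01
    weight_decay: float = 0.0001
    dropout: float = 0.1
    activation: str = "relu"
    discretization: str = "km_quantiles"
    interpolation: str = "CDI"
    alpha: float = 0.25
    beta: float = 0.48
    m: int = 10
    epochs: int = 512
    batch_size: int = 1024
    patience: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_layers", "width", "learning_rate", "weight_decay", "dropout", "alpha", "beta"):
            lo, hi = _BOX[name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside the search box [{lo}, {hi}]")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")


def build_network(p: int, hp: HyperParams, loss_name: str = "nmtlr_rank") -> MLP:
    """Untrained trunk + linear head; head width m (1 for the Cox loss).

    The reverse-cumulative-sum output transform carries no trainable
    parameters; it is applied inside the loss/prediction path.
    """
    if p < 1:
        raise ValueError("need at least one input gene")
    n_out = 1 if loss_name == "cox" else hp.m
    return MLP(
        n_in=p,
        n_out=n_out,
        n_layers=hp.n_layers,
        width=hp.width,
        activation=hp.activation,
        dropout=hp.dropout,
        seed=hp.seed,
    )


def _breslow_baseline(theta: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Breslow cumulative baseline hazard for Cox-head survival curves."""
    order = np.argsort(time, kind="stable")
    t, d, th = time[order], event[order], theta[order]
    e = np.exp(th - th.max())
    # risk-set sums at each position (descending tail sums)
    tail = np.cumsum(e[::-1])[::-1]
    jump_t, jump_h = [], []
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        n_ev = int(d[i:j].sum())
        if n_ev:
            jump_t.append(t[i])
            jump_h.append(n_ev / tail[i] * np.exp(-th.max()))
        i = j
    return np.asarray(jump_t), np.cumsum(jump_h)


@dataclass
class FittedModel:
    """Trained network bundled with everything needed to predict."""

    mlp: MLP
    hp: HyperParams
    loss_name: str
    grid: TimeGrid | None
    genes: list[str]
    standardization: tuple[np.ndarray, np.ndarray]
    loss_trace: list[float] = field(default_factory=list)
    baseline: tuple[np.ndarray, np.ndarray] | None = None  # Cox only

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        mean, sd = self.standardization
        return (np.asarray(X, dtype=float) - mean) / sd

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        return self.mlp.predict(self._standardize(X))

    def predict_survival(self, X: np.ndarray, times=None, interpolation: str | None = None):
        """Survival probabilities; at the grid cuts, or interpolated at ``times``."""
        out = self.predict_raw(X)
        if self.loss_name == "cox":
            jump_t, H0 = self.baseline
            theta = out[:, 0]
            tq = np.atleast_1d(np.asarray(times, dtype=float))
            H = np.concatenate([[0.0], H0])[np.searchsorted(jump_t, tq, side="right")]
            return np.exp(-np.outer(np.exp(theta - theta.mean()) * np.exp(theta.mean()), H))
        pred = predict_discrete(out) if self.loss_name in ("nmtlr_rank", "nmtlr") else None
        if pred is None:
            from .losses import pmf_from_phi

            pred = pmf_from_phi(out, psi=out)
        if times is None:
            return pred.S_at_cuts
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return interpolate_survival(
                pred.S_at_cuts, self.grid, times, interpolation or self.hp.interpolation
            )

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "weights.json").write_text(json.dumps(self.mlp.get_state()))
        mean, sd = self.standardization
        sidecar = {
            "hyperparams": asdict(self.hp),
            "loss_name": self.loss_name,
            "grid": self.grid.to_dict() if self.grid else None,
            "genes": self.genes,
            "standardization": {"mean": mean.tolist(), "sd": sd.tolist()},
            "loss_trace": self.loss_trace,
            "baseline": None
            if self.baseline is None
            else {"times": self.baseline[0].tolist(), "cumhaz": self.baseline[1].tolist()},
        }
        (d / "model.json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, directory) -> "FittedModel":
        d = Path(directory)
        mlp = MLP.from_state(json.loads((d / "weights.json").read_text()))
        sc = json.loads((d / "model.json").read_text())
        baseline = sc["baseline"]
        return cls(
            mlp=mlp,
            hp=HyperParams(**sc["hyperparams"]),
            loss_name=sc["loss_name"],
            grid=TimeGrid.from_dict(sc["grid"]) if sc["grid"] else None,
            genes=sc["genes"],
            standardization=(
                np.asarray(sc["standardization"]["mean"]),
                np.asarray(sc["standardization"]["sd"]),
            ),
            loss_trace=sc["loss_trace"],
            baseline=None
            if baseline is None
            else (np.asarray(baseline["times"]), np.asarray(baseline["cumhaz"])),
        )


def _loss_and_grad(loss_name, psi, k_idx, event, time, hp):
    if loss_name == "cox":
        loss, g = loss_cox_grad(psi[:, 0], time, event)
        return loss, g[:, None]
    alpha = {"nmtlr": 1.0, "pmf": 1.0}.get(loss_name, hp.alpha)
    use_cumsum = loss_name in ("nmtlr_rank", "nmtlr")
    return discrete_loss_grad(psi, k_idx, event, time, alpha, hp.beta, use_cumsum=use_cumsum)


def train(
    cohort: SurvivalCohort,
    hp: HyperParams,
    loss_name: str = "nmtlr_rank",
    grid: TimeGrid | None = None,
    standardization=None,
    val: SurvivalCohort | None = None,
    model: MLP | None = None,
) -> FittedModel:
    """Fit a survival network on one (standardizable) cohort.

    Standardization statistics and the time grid are computed from the
    training cohort unless supplied; both are stored in the returned model.
    With a validation cohort, early stopping monitors the validation loss
    with the configured patience and restores the best weights.  NaN losses
    abort with a learning-rate hint.
    """
    if loss_name not in LOSSES:
        raise ValueError(f"loss_name must be one of {LOSSES}")
    if standardization is None:
        _, standardization = standardize(cohort.X)
    mean, sd = standardization
    X = (cohort.X - mean) / sd
    if loss_name != "cox" and grid is None:
        grid = make_grid(cohort.time, cohort.event, hp.m, hp.discretization)
    hp_eff = hp if grid is None or grid.m == hp.m else replace(hp, m=grid.m)
    k_idx = assign_interval(cohort.time, grid) if grid is not None else None
    model = model or build_network(cohort.p, hp_eff, loss_name)
    opt = Adam(lr=hp.learning_rate, weight_decay=hp.weight_decay)
    rng = np.random.default_rng(hp.seed + 1)

    if val is not None:
        Xv = (val.X - mean) / sd
        kv = assign_interval(val.time, grid) if grid is not None else None
    best_val, best_snap, since_best = math.inf, None, 0

    n = cohort.n
    trace: list[float] = []
    for epoch in range(hp.epochs):
        if n <= hp.batch_size:
            batches = [np.arange(n)]
        else:
            perm = rng.permutation(n)
            batches = np.array_split(perm, math.ceil(n / hp.batch_size))
        ep_loss = 0.0
        for idx in batches:
            psi, cache = model.forward(X[idx], train=True, rng=rng)
            loss, d_psi = _loss_and_grad(
                loss_name, psi, None if k_idx is None else k_idx[idx],
                cohort.event[idx], cohort.time[idx], hp,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"loss became non-finite at epoch {epoch}; try a smaller learning rate"
                )
            gW, gb = model.backward(cache, d_psi)
            opt.step(model.weights + model.biases, gW + gb)
            ep_loss += loss * len(idx)
        trace.append(ep_loss / n)
        if val is not None:
            psi_v = model.predict(Xv)
            vloss, _ = _loss_and_grad(loss_name, psi_v, kv, val.event, val.time, hp)
            if vloss < best_val - 1e-9:
                best_val, best_snap, since_best = vloss, model.copy_weights(), 0
            else:
                since_best += 1
                if since_best >= hp.patience:
                    break
    if best_snap is not None:
        model.set_weights(best_snap)

    baseline = None
    if loss_name == "cox":
        theta = model.predict(X)[:, 0]
        baseline = _breslow_baseline(theta, cohort.time, cohort.event.astype(int))
    return FittedModel(
        mlp=model,
        hp=hp_eff,
        loss_name=loss_name,
        grid=grid,
        genes=list(cohort.genes),
        standardization=(np.asarray(mean), np.asarray(sd)),
        loss_trace=trace,
        baseline=baseline,
    )


def _intersect_genes(cohorts: list[SurvivalCohort]) -> list[str]:
    genes = set(cohorts[0].genes)
    for c in cohorts[1:]:
        genes &= set(c.genes)
    if not genes:
        raise ValueError("empty gene intersection across cohorts")
    return [g for g in cohorts[0].genes if g in genes]


def combined_train(
    target: SurvivalCohort,
    auxiliaries: list[SurvivalCohort],
    hp: HyperParams,
    loss_name: str = "nmtlr_rank",
    per_cohort_standardization: bool = False,
    val: SurvivalCohort | None = None,
) -> FittedModel:
    """Train one network on the target plus auxiliary cohorts.

    Gene lists are inner-joined; the time grid is fitted on the pooled
    training times.  Standardization is pooled by default, with a per-cohort
    switch (each cohort centred/scaled on its own statistics before
    concatenation; the stored statistics are then the pooled ones of the
    transformed matrix, i.e. pass-through).  Evaluation is always the
    caller's business and should use held-out *target* subjects only.
    """
    if not auxiliaries:
        return train(target, hp, loss_name, val=val)
    cohorts = [target] + list(auxiliaries)
    genes = _intersect_genes(cohorts)
    cols = [[c.genes.index(g) for g in genes] for c in cohorts]
    mats = [c.X[:, ci] for c, ci in zip(cohorts, cols)]
    if per_cohort_standardization:
        mats = [standardize(m)[0] for m in mats]
    X = np.vstack(mats)
    pooled = SurvivalCohort(
        subject_ids=[f"{i}:{s}" for i, c in enumerate(cohorts) for s in c.subject_ids],
        genes=genes,
        X=X,
        time=np.concatenate([c.time for c in cohorts]),
        event=np.concatenate([c.event for c in cohorts]),
        cohort_label=f"{target.cohort_label}+aux",
    )
    val_sub = None
    if val is not None:
        vcols = [val.genes.index(g) for g in genes]
        val_sub = SurvivalCohort(
            subject_ids=val.subject_ids, genes=genes, X=val.X[:, vcols],
            time=val.time, event=val.event, cohort_label=val.cohort_label,
        )
    return train(pooled, hp, loss_name, val=val_sub)


def evaluate_model(model: FittedModel, cohort: SurvivalCohort, n_eval: int = 100):
    """MetricReport for a fitted model on a (held-out) cohort."""
    if cohort.genes == model.genes:
        X = cohort.X
    else:  # reorder/select the cohort's columns to the model's gene list
        X = cohort.X[:, [cohort.genes.index(g) for g in model.genes]]
    eval_times = np.linspace(0.0, float(cohort.time.max()), n_eval)
    S = model.predict_survival(X, times=eval_times)
    return evaluate_predictions(S, eval_times, cohort.time, cohort.event)


def cross_validate(
    cohort: SurvivalCohort,
    hp: HyperParams,
    loss_name: str = "nmtlr_rank",
    k: int = 5,
    repeats: int = 10,
    n_time_bins: int = 4,
    seed: int = 0,
    auxiliaries: list[SurvivalCohort] | None = None,
) -> pd.DataFrame:
    """Repeated stratified k-fold evaluation; k * repeats rows.

    Each repeat differs only in the training seed; folds are fixed by
    ``seed``.  Standardization and the time grid are refitted inside every
    training split; metrics are computed on the untouched test fold.
    """
    folds = stratified_kfold(cohort, k=k, n_time_bins=n_time_bins, seed=seed)
    rows = []
    for fi, (tr, te) in enumerate(folds):
        tr_cohort, te_cohort = cohort.subset(tr), cohort.subset(te)
        if te_cohort.event.sum() == 0 or tr_cohort.event.sum() == 0:
            raise ValueError(f"fold {fi} has no events; refit folds with fewer bins")
        for rep in range(repeats):
            hp_rep = replace(hp, seed=seed + 1000 * fi + rep)
            if auxiliaries:
                fitted = combined_train(tr_cohort, auxiliaries, hp_rep, loss_name)
            else:
                fitted = train(tr_cohort, hp_rep, loss_name)
            report = evaluate_model(fitted, te_cohort)
            rows.append(
                {
                    "fold": fi,
                    "repeat": rep,
                    "seed": hp_rep.seed,
                    "c_index": report.c_index_td,
                    "ibs": report.ibs,
                }
            )
    return pd.DataFrame(rows)


def sample_hyperparams(rng: np.random.Generator, base: HyperParams | None = None) -> HyperParams:
    """Draw one configuration from the search box (log-uniform width/lr)."""
    base = base or HyperParams()
    return replace(
        base,
        n_layers=int(rng.integers(1, 9)),
        width=int(round(np.exp(rng.uniform(np.log(8), np.log(2048))))),
        learning_rate=float(np.exp(rng.uniform(np.log(1e-5), np.log(0.1)))),
        weight_decay=float(rng.uniform(0.0, 0.9)),
        dropout=float(rng.uniform(0.0, 0.6)),
        activation=str(rng.choice(_ACTIVATIONS)),
        discretization=str(rng.choice(("equidistant", "km_quantiles"))),
        interpolation=str(rng.choice(("CDI", "CHI"))),
        alpha=float(rng.uniform(0.0, 1.0)),
        beta=float(np.exp(rng.uniform(np.log(0.1), np.log(100.0)))),
    )


def tune(
    train_sub: SurvivalCohort,
    val_sub: SurvivalCohort,
    budget: int = 25,
    seed: int = 0,
    loss_name: str = "nmtlr_rank",
    objective: str = "c_index",
    base: HyperParams | None = None,
):
    """Random search over the hyperparameter box.

    Each trial trains on ``train_sub`` and scores on ``val_sub``; the
    objective is the validation time-dependent C-index (maximized) or the
    IBS (minimized).  Returns ``(best HyperParams, trial-log DataFrame)``.
    Deterministic given ``seed``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if objective not in ("c_index", "ibs"):
        raise ValueError("objective must be 'c_index' or 'ibs'")
    rng = np.random.default_rng(seed)
    log = []
    for trial in range(budget):
        hp = replace(sample_hyperparams(rng, base), seed=seed + trial)
        row = {"trial": trial, **asdict(hp)}
        try:
            fitted = train(train_sub, hp, loss_name, val=val_sub)
            report = evaluate_model(fitted, val_sub)
            row.update(c_index=report.c_index_td, ibs=report.ibs, error="")
        except Exception as exc:  # noqa: BLE001 — a failed trial is data
            row.update(c_index=np.nan, ibs=np.nan, error=str(exc))
        log.append(row)
    log_df = pd.DataFrame(log)
    ok = log_df.dropna(subset=[objective])
    if ok.empty:
        raise RuntimeError(f"all {budget} trials failed:\n{log_df[['trial', 'error']]}")
    best_row = ok.loc[ok[objective].idxmax() if objective == "c_index" else ok[objective].idxmin()]
    best_hp = HyperParams(
        **{k: best_row[k] for k in asdict(HyperParams()) if k in best_row.index}
    )
    # restore exact types lost through the DataFrame round-trip
    best_hp = replace(
        best_hp,
        n_layers=int(best_row["n_layers"]), width=int(best_row["width"]),
        m=int(best_row["m"]), epochs=int(best_row["epochs"]),
        batch_size=int(best_row["batch_size"]), patience=int(best_row["patience"]),
        seed=int(best_row["seed"]),
    )
    return best_hp, log_df
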