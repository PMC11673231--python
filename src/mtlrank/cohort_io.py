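"""Cohort and gene-set input/output, normalization and fold construction.

Expression matrices arrive as delimited text with one axis of gene symbols
and one of subject identifiers; orientation is an explicit flag rather than
guessed, since a silently transposed matrix is the classic failure mode.
Survival annotations are a two-column (time in days, 0/1 event indicator)
table keyed by subject id.  Gene-set collections use the standard GMT
dialect (name TAB description TAB gene ...).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCohort:
    """Right-censored survival cohort: (X_i, t_i, d_i) triplets.

    X is n subjects x p genes on the log2 scale after normalization; time is
    in days; event is 1 for an observed failure (death) and 0 for
    right-censoring.
    """

    subject_ids: list[str]
    genes: list[str]
    X: np.ndarray
    time: np.ndarray
    event: np.ndarray
    cohort_label: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = self.X.shape[0]
        if not (len(self.time) == len(self.event) == len(self.subject_ids) == n):
            raise ValueError("time/event/subject_ids lengths must match rows of X")
        if self.X.shape[1] != len(self.genes):
            raise ValueError("gene list length must match columns of X")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols in cohort")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids in cohort")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains missing or non-finite values")
        if np.any((self.event != 0) & (self.event != 1)):
            raise ValueError("event indicators must be 0 or 1")
        if np.any(self.time <= 0):
            raise ValueError("all observed times must be positive")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, idx) -> "SurvivalCohort":
        idx = np.asarray(idx)
        return SurvivalCohort(
            subject_ids=[self.subject_ids[i] for i in idx],
            genes=list(self.genes),
            X=self.X[idx],
            time=self.time[idx],
            event=self.event[idx],
            cohort_label=self.cohort_label,
        )

    def to_files(self, expr_path, surv_path) -> None:
        """Write the TSV pair that :func:`load_cohort` reads back."""
        pd.DataFrame(self.X, index=self.subject_ids, columns=self.genes).to_csv(
            expr_path, sep="\t"
        )
        pd.DataFrame(
            {"time_days": self.time, "event01": self.event}, index=self.subject_ids
        ).rename_axis("subject_id").to_csv(surv_path, sep="\t")


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]] = field(default_factory=dict)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            upper = [g.upper() for g in genes]
            seen: dict[str, None] = {}
            for g in upper:
                seen.setdefault(g)
            self.sets[name] = list(seen)


def _read_table(path) -> pd.DataFrame:
    # header parsed by hand so duplicated symbols survive (pandas would
    # mangle "TP53, TP53" into "TP53, TP53.1" and defeat the mean-collapse)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    sep = "\t" if "\t" in header else ","
    names = header.split(sep)[1:]
    df = pd.read_csv(path, sep=sep, skiprows=1, header=None, index_col=0)
    if df.shape[1] != len(names):
        raise ValueError(f"{path}: header has {len(names)} columns, body {df.shape[1]}")
    df.columns = names
    for ci in range(df.shape[1]):
        col = df.iloc[:, ci]
        bad = pd.to_numeric(col, errors="coerce").isna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"non-numeric value in {path} at row {row!r}, column {names[ci]!r}"
            )
    return df.astype(float)


def load_expression(path, orientation: str = "samples_rows"):
    """Read a delimited expression matrix, returning (X, genes, subject_ids).

    ``orientation`` names what the file's ROWS are.  The returned matrix is
    always samples x genes.  Duplicate gene symbols are collapsed by their
    mean (logged); duplicate subject ids are an error.
    """
    if orientation not in ("samples_rows", "genes_rows"):
        raise ValueError("orientation must be 'samples_rows' or 'genes_rows'")
    df = _read_table(path)
    if orientation == "genes_rows":
        df = df.T
    df.columns = [str(c).upper() for c in df.columns]
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject ids: {dups}")
    if pd.Index(df.columns).duplicated().any():
        n_dup = int(pd.Index(df.columns).duplicated().sum())
        logger.info("collapsing %d duplicated gene symbol(s) by mean", n_dup)
        df = df.T.groupby(level=0, sort=False).mean().T
    return df.to_numpy(), list(df.columns), [str(i) for i in df.index]


def load_survival(path) -> pd.DataFrame:
    """Read the (time_days, event01) annotation table keyed by subject id."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.columns = [c.lower() for c in df.columns]
    if not {"time_days", "event01"} <= set(df.columns):
        raise ValueError("survival table needs columns 'time_days' and 'event01'")
    return df[["time_days", "event01"]]


def load_cohort(expr_path, surv_path, orientation="samples_rows", cohort_label="") -> SurvivalCohort:
    X, genes, ids = load_expression(expr_path, orientation)
    surv = load_survival(surv_path)
    missing = [s for s in ids if s not in surv.index]
    if missing:
        raise ValueError(f"subjects without survival annotation: {missing[:5]}")
    surv = surv.loc[ids]
    return SurvivalCohort(
        subject_ids=ids,
        genes=genes,
        X=X,
        time=surv["time_days"].to_numpy(float),
        event=surv["event01"].to_numpy(int),
        cohort_label=cohort_label,
    )


def log2p1(X: np.ndarray) -> np.ndarray:
    """Entrywise log2(x + 1); rejects negative entries."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("log2p1 requires nonnegative entries")
    return np.log2(X + 1.0)


def standardize(train_X: np.ndarray, apply_X: np.ndarray | None = None):
    """Zero-mean/unit-variance per gene, statistics from the training set only.

    Returns ``(standardized apply_X, (mean, sd))``.  Zero-variance genes keep
    sd = 1 so they map to all-zero columns instead of dividing by zero; they
    are retained (not dropped) so gene indices stay aligned with downstream
    attribution matrices.
    """
    train_X = np.asarray(train_X, dtype=float)
    if apply_X is None:
        apply_X = train_X
    apply_X = np.asarray(apply_X, dtype=float)
    if train_X.shape[1] != apply_X.shape[1]:
        raise ValueError("train and apply matrices must share their gene columns")
    mean = train_X.mean(axis=0)
    sd = train_X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (apply_X - mean) / sd, (mean, sd)


def stratified_kfold(cohort: SurvivalCohort, k: int, n_time_bins: int = 4, seed: int = 0):
    """k-fold partition stratified by event indicator x observed-time bin.

    Stratification cells are the cross-tab of the event indicator with
    quantile bins of the observed time, so each fold sees a similar censoring
    rate and time distribution.  If a cell has fewer than k members the time
    bins are coarsened (with a warning), down to event-only stratification,
    and finally to a plain shuffled partition (the leave-one-out case).
    Deterministic given ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if cohort.n < k:
        raise ValueError("need at least k subjects")
    time, event = cohort.time, cohort.event
    for bins in range(n_time_bins, 0, -1):
        if bins > 1:
            tb = pd.qcut(time, q=bins, labels=False, duplicates="drop")
        else:
            tb = np.zeros(len(time), dtype=int)
        labels = event * 100 + np.asarray(tb, dtype=int)
        counts = pd.Series(labels).value_counts()
        if counts.min() >= k:
            if bins < n_time_bins:
                warnings.warn(
                    f"stratification cells merged: {n_time_bins} -> {bins} time bins",
                    stacklevel=2,
                )
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            return [(tr, te) for tr, te in skf.split(np.zeros(cohort.n), labels)]
    warnings.warn("too few subjects per cell; falling back to unstratified folds", stacklevel=2)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in kf.split(np.zeros(cohort.n))]


def load_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name TAB description TAB gene [TAB gene ...]."""
    sets: dict[str, list[str]] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name, _desc, *genes = fields
        genes = [g for g in genes if g.strip()]
        if not genes:
            raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
        sets[name] = genes
    if not sets:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
    return GeneSetCollection(sets=sets, source=str(path))
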