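"""Data splits, balance testing, classification metrics, and AUC comparison.

The harness around any external classifier: stratified hold-out and k-fold
construction, Pearson chi-square balance checks between training and test
covariate distributions, threshold metrics and Mann-Whitney AUC from
prediction records, DeLong's paired test for correlated AUCs, nested
stress-test subsampling schedules, and frame-level soft voting for
video-clip aggregation.  AD is the positive class throughout.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from specaug.io_manifest import LABELS, DatasetManifest, ValidationError

#: Fold code for hold-out test samples in a SplitPlan.
HOLDOUT = -1
#: Fold code for samples not selected (stress-test schedules).
UNSELECTED = -2


@dataclass
class ContingencyTable:
    """r x c nonnegative counts with row/column labels."""

    counts: np.ndarray
    row_labels: list[str] = field(default_factory=list)
    col_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or min(self.counts.shape) < 2:
            raise ValidationError(
                f"contingency table must be at least 2x2, got shape {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValidationError("contingency counts must be nonnegative")
        if self.counts.sum() == 0:
            raise ValidationError("contingency table has zero grand total")
        if not self.row_labels:
            self.row_labels = [f"row{i}" for i in range(self.counts.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"col{j}" for j in range(self.counts.shape[1])]

    def column_percentages(self) -> np.ndarray:
        """Per-cell percentage of its column total, rounded to 1 decimal."""
        totals = self.counts.sum(axis=0, keepdims=True)
        return np.round(100.0 * self.counts / totals, 1)


@dataclass(frozen=True)
class PredictionRecord:
    """One classifier output: id, optional clip group, truth, P(AD)."""

    sample_id: str
    true_label: str
    score: float
    group_id: str | None = None

    def __post_init__(self) -> None:
        if self.true_label not in LABELS:
            raise ValidationError(f"unknown label {self.true_label!r}")
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"score must be in [0,1], got {self.score}")


@dataclass
class SplitPlan:
    """Integer fold assignment per sample: 0..k-1, HOLDOUT (-1), or UNSELECTED (-2)."""

    folds: np.ndarray

    def __post_init__(self) -> None:
        self.folds = np.asarray(self.folds, dtype=np.int64)

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.folds == fold)

    @property
    def holdout_indices(self) -> np.ndarray:
        return self.indices(HOLDOUT)

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.folds >= 0)


# ---------------------------------------------------------------------------
# Split construction
# ---------------------------------------------------------------------------


def stratified_holdout(
    manifest: DatasetManifest, n_per_class: int, rng: np.random.Generator
) -> SplitPlan:
    """Mark exactly ``n_per_class`` random samples per class as hold-out.

    The remainder forms the training pool (fold 0).
    """
    folds = np.zeros(len(manifest), dtype=np.int64)
    for label in LABELS:
        idx = np.array(manifest.by_label(label))
        if len(idx) < n_per_class:
            raise ValidationError(
                f"class {label} has {len(idx)} samples < n_per_class={n_per_class}"
            )
        chosen = rng.choice(idx, size=n_per_class, replace=False)
        folds[chosen] = HOLDOUT
    return SplitPlan(folds)


def stratified_kfold(
    pool: DatasetManifest, k: int, rng: np.random.Generator
) -> SplitPlan:
    """Class-stratified k-fold partition; per-class fold sizes differ by <= 1."""
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    folds = np.empty(len(pool), dtype=np.int64)
    for label in LABELS:
        idx = np.array(pool.by_label(label))
        if len(idx) < k:
            raise ValidationError(f"class {label} has {len(idx)} samples < k={k}")
        perm = rng.permutation(idx)
        for f in range(k):
            folds[perm[f::k]] = f
    return SplitPlan(folds)


def stress_schedule(
    pool: DatasetManifest,
    fractions: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    rng: np.random.Generator | None = None,
) -> list[SplitPlan]:
    """Nested, class-stratified random subsets at increasing fractions.

    Each class is permuted once; the subset at fraction f takes the first
    round(f * n_class) samples of that permutation, so smaller subsets are
    contained in larger ones (variance reduction across the schedule).
    Selected samples get fold 0; the rest are UNSELECTED.
    """
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValidationError(f"fractions must be in (0, 1], got {fractions}")
    rng = rng if rng is not None else np.random.default_rng(0)
    perms = {label: rng.permutation(pool.by_label(label)) for label in LABELS}
    plans = []
    for f in fractions:
        folds = np.full(len(pool), UNSELECTED, dtype=np.int64)
        for label in LABELS:
            n_take = int(round(f * len(perms[label])))
            folds[perms[label][:n_take]] = 0
        plans.append(SplitPlan(folds))
    return plans


# ---------------------------------------------------------------------------
# Chi-square balance testing
# ---------------------------------------------------------------------------


def chi_square_independence(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction.

    X^2 = sum (O - E)^2 / E with E from the row/column margins;
    df = (r-1)(c-1); p from the upper tail.
    """
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValidationError("contingency table has a zero margin")
    stat, p, df, expected = stats.chi2_contingency(counts, correction=False)
    if (expected <= 0).any():
        raise ValidationError("chi-square requires all expected counts > 0")
    return float(stat), int(df), float(p)


def balance_report(
    train: DatasetManifest,
    test: DatasetManifest,
    covariates: list[str],
) -> pd.DataFrame:
    """Chi-square balance check per covariate between train and test sets.

    ``"label"`` tests the class distribution itself; any other covariate
    must be present in the samples' metadata.  Returns one row per
    covariate with the statistic, df, p-value, and per-cell
    "count (column %)" strings in the conventional style.
    """

    def values(manifest, cov):
        if cov == "label":
            return [s.label for s in manifest]
        missing = [s.image_path for s in manifest if cov not in s.metadata]
        if missing:
            raise ValidationError(
                f"covariate {cov!r} missing for {len(missing)} samples "
                f"(first: {missing[0]})"
            )
        return [s.metadata[cov] for s in manifest]

    rows = []
    for cov in covariates:
        tr, te = values(train, cov), values(test, cov)
        cats = list(OrderedDict.fromkeys(tr + te))
        counts = np.array(
            [[tr.count(c), te.count(c)] for c in cats], dtype=np.int64
        )
        table = ContingencyTable(counts, row_labels=cats, col_labels=["train", "test"])
        stat, df, p = chi_square_independence(table)
        pct = table.column_percentages()
        cells = {
            f"{c} ({col})": f"{counts[i, j]:,} ({pct[i, j]:.1f})"
            for i, c in enumerate(cats)
            for j, col in enumerate(("train", "test"))
        }
        rows.append({"covariate": cov, "chi2": stat, "df": df, "p": p, **cells})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Classification metrics
# ---------------------------------------------------------------------------


def _split_scores(preds: list[PredictionRecord]) -> tuple[np.ndarray, np.ndarray]:
    pos = np.array([r.score for r in preds if r.true_label == "AD"])
    neg = np.array([r.score for r in preds if r.true_label == "HP"])
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("both classes must be present")
    return pos, neg


def auc_mann_whitney(preds: list[PredictionRecord]) -> float:
    """AUC as the Mann-Whitney U statistic (ties counted 1/2)."""
    pos, neg = _split_scores(preds)
    all_scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_scores)  # midranks handle ties
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def classification_metrics(
    preds: list[PredictionRecord], threshold: float = 0.5
) -> dict[str, float]:
    """AUC plus confusion-matrix metrics at ``score >= threshold`` => AD."""
    pos, neg = _split_scores(preds)
    tp = int((pos >= threshold).sum())
    fn = len(pos) - tp
    fp = int((neg >= threshold).sum())
    tn = len(neg) - fp

    def ratio(a, b):
        return a / b if b > 0 else float("nan")

    return {
        "AUC": auc_mann_whitney(preds),
        "ACC": ratio(tp + tn, tp + tn + fp + fn),
        "SEN": ratio(tp, tp + fn),
        "SPE": ratio(tn, tn + fp),
        "PPV": ratio(tp, tp + fp),
        "NPV": ratio(tn, tn + fn),
    }


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    psi = (pos[:, None] > neg[None, :]).astype(np.float64)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)


def delong_test(
    preds_a: list[PredictionRecord], preds_b: list[PredictionRecord]
) -> tuple[float, float, float, float]:
    """DeLong's paired comparison of two correlated AUCs.

    Both prediction lists must cover the same samples in the same order.
    Returns (auc_a, auc_b, z, two-sided p).  The variance of the AUC
    difference comes from the empirical covariance of the per-sample
    placement values.
    """
    ids_a = [(r.sample_id, r.true_label) for r in preds_a]
    ids_b = [(r.sample_id, r.true_label) for r in preds_b]
    if ids_a != ids_b:
        raise ValidationError("delong_test requires paired predictions")
    pos_a, neg_a = _split_scores(preds_a)
    pos_b, neg_b = _split_scores(preds_b)
    m, n = len(pos_a), len(neg_a)

    v10_a, v01_a = _placements(pos_a, neg_a)
    v10_b, v01_b = _placements(pos_b, neg_b)
    auc_a, auc_b = float(v10_a.mean()), float(v10_b.mean())

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    if var <= 0:
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


def delong_variance(preds: list[PredictionRecord]) -> float:
    """DeLong variance of a single AUC (used for cross-checking)."""
    pos, neg = _split_scores(preds)
    v10, v01 = _placements(pos, neg)
    var10 = v10.var(ddof=1) if len(pos) > 1 else 0.0
    var01 = v01.var(ddof=1) if len(neg) > 1 else 0.0
    return float(var10 / len(pos) + var01 / len(neg))


# ---------------------------------------------------------------------------
# Soft voting
# ---------------------------------------------------------------------------


def soft_vote(preds: list[PredictionRecord]) -> list[PredictionRecord]:
    """Aggregate frame-level predictions to one record per group.

    The group score is the unweighted mean of member scores; all members
    of a group must share a label.
    """
    groups: "OrderedDict[str, list[PredictionRecord]]" = OrderedDict()
    for r in preds:
        if r.group_id is None:
            raise ValidationError(f"record {r.sample_id} has no group_id")
        groups.setdefault(r.group_id, []).append(r)
    out = []
    for gid, members in groups.items():
        labels = {r.true_label for r in members}
        if len(labels) != 1:
            raise ValidationError(f"group {gid!r} mixes labels {sorted(labels)}")
        out.append(
            PredictionRecord(
                sample_id=gid,
                group_id=gid,
                true_label=members[0].true_label,
                score=float(np.mean([r.score for r in members])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Prediction CSV I/O
# ---------------------------------------------------------------------------


def read_predictions(path) -> list[PredictionRecord]:
    """Read a prediction CSV: sample_id,group_id,true_label,score."""
    df = pd.read_csv(path, dtype={"sample_id": str, "group_id": str})
    records = []
    for _, row in df.iterrows():
        gid = row.get("group_id")
        records.append(
            PredictionRecord(
                sample_id=str(row["sample_id"]),
                group_id=None if pd.isna(gid) else str(gid),
                true_label=str(row["true_label"]),
                score=float(row["score"]),
            )
        )
    return records
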