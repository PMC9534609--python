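"""Binary-classification evaluation: confusion matrices, six metrics,
rank-based AUC, and a repeated stratified-CV harness.

The positive class is "presence of heart disease".  From a confusion
matrix (TP, FN, FP, TN) the six reported metrics are

    sensitivity = TP/(TP+FN)          specificity = TN/(TN+FP)
    precision   = TP/(TP+FP)          accuracy    = (TP+TN)/n
    F-score     = 2*prec*sens/(prec+sens)
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

rendered as percentages rounded half-up to two decimals, full precision
retained internally.  A metric whose denominator vanishes is reported as
0 and flagged undefined rather than raising.

The harness runs n_iterations rounds; each round drives a stratified
10-fold cross-validation with its own seed and pools the fold predictions
into a single confusion matrix covering all n records, so every round's
matrix sums to the full sample size.  The report is the per-round metric
rows plus their arithmetic column means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .data import ClinicalTable
from .feature_selection import FeatureSubset
from .preprocess import Normalizer

__all__ = [
    "ConfusionMatrix",
    "MetricsRow",
    "confusion",
    "metrics",
    "roc_auc",
    "run_iterations",
    "EvaluationReport",
]

METRIC_COLUMNS = ["sensitivity", "specificity", "precision", "accuracy", "f_score", "mcc"]


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals (report rendering convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.FP, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FN + self.FP + self.TN

    def to_dict(self) -> dict:
        return {"TP": self.TP, "FN": self.FN, "FP": self.FP, "TN": self.TN}


@dataclass
class MetricsRow:
    """Six metrics as percentages; ``undefined`` names zero-denominator ones."""

    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f_score: float
    mcc: float
    undefined: list[str] = field(default_factory=list)

    def as_list(self, rounded: bool = True) -> list[float]:
        vals = [getattr(self, c) for c in METRIC_COLUMNS]
        return [round2(v) for v in vals] if rounded else vals


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """Count TP/FN/FP/TN with positive = 1 (disease present)."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    return ConfusionMatrix(
        TP=int(np.sum((t == 1) & (p == 1))),
        FN=int(np.sum((t == 1) & (p == 0))),
        FP=int(np.sum((t == 0) & (p == 1))),
        TN=int(np.sum((t == 0) & (p == 0))),
    )


def _ratio(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsRow:
    """The six metrics of one confusion matrix, as percentages."""
    undefined: list[str] = []
    sens = _ratio(cm.TP, cm.TP + cm.FN, "sensitivity", undefined)
    spec = _ratio(cm.TN, cm.TN + cm.FP, "specificity", undefined)
    prec = _ratio(cm.TP, cm.TP + cm.FP, "precision", undefined)
    acc = _ratio(cm.TP + cm.TN, cm.n, "accuracy", undefined)
    f = _ratio(2 * prec * sens, prec + sens, "f_score", undefined)
    mcc_den = math.sqrt(
        float(cm.TP + cm.FP) * (cm.TP + cm.FN) * (cm.TN + cm.FP) * (cm.TN + cm.FN)
    )
    mcc = _ratio(cm.TP * cm.TN - cm.FP * cm.FN, mcc_den, "mcc", undefined)
    return MetricsRow(
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        precision=100.0 * prec,
        accuracy=100.0 * acc,
        f_score=100.0 * f,
        mcc=100.0 * mcc,
        undefined=undefined,
    )


def roc_auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    t = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(t == 1))
    n_neg = int(np.sum(t == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(s)  # midranks
    return float((ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class EvaluationReport:
    """Per-iteration confusion matrices and metric rows, plus the average row."""

    confusions: list[ConfusionMatrix]
    rows: list[MetricsRow]
    average: list[float]  # column means, rounded to 2 decimals

    def to_csv(self, path) -> None:
        import csv

        header = ["iteration"] + [c.capitalize() for c in METRIC_COLUMNS]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            for i, row in enumerate(self.rows, start=1):
                w.writerow([f"Iteration-{i}"] + [f"{v:.2f}" for v in row.as_list()])
            w.writerow(["Average"] + [f"{v:.2f}" for v in self.average])

    def summary(self) -> str:
        lines = ["iteration  " + "  ".join(f"{c:>11}" for c in METRIC_COLUMNS)]
        for i, row in enumerate(self.rows, start=1):
            lines.append(
                f"{i:>9}  " + "  ".join(f"{v:11.2f}" for v in row.as_list())
            )
        lines.append("  average  " + "  ".join(f"{v:11.2f}" for v in self.average))
        return "\n".join(lines)


def average_row(rows: list[MetricsRow]) -> list[float]:
    """Arithmetic mean of each (2-decimal) metric column, rounded again."""
    cols = np.array([row.as_list(rounded=True) for row in rows])
    return [round2(v) for v in cols.mean(axis=0)]


def run_iterations(
    table: ClinicalTable,
    subset: FeatureSubset,
    classifier_factory: Callable[[int], object],
    n_iterations: int = 10,
    cv_folds: int = 10,
    seed: int = 0,
    refit_normalizer: bool = True,
) -> EvaluationReport:
    """Repeated stratified-CV evaluation with pooled fold predictions.

    classifier_factory(iteration_seed) must return a fresh object with
    fit(X, y) and predict(X).  Within each fold the min-max normalisation
    is refit on the training part only (leakage guard) unless
    ``refit_normalizer=False``.
    """
    X_all = subset.apply(table.values)
    y = table.labels
    confusions: list[ConfusionMatrix] = []
    rows: list[MetricsRow] = []
    for it in range(n_iterations):
        it_seed = (seed + 1000003 * it) % (2**31)
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=it_seed)
        pooled_pred = np.empty(table.n, dtype=int)
        for train, test in skf.split(X_all, y):
            X_tr, X_te = X_all[train], X_all[test]
            if refit_normalizer:
                norm = Normalizer(method="minmax").fit(X_tr)
                X_tr, X_te = norm.transform(X_tr), norm.transform(X_te)
            clf = classifier_factory(it_seed)
            clf.fit(X_tr, y[train])
            pooled_pred[test] = np.asarray(clf.predict(X_te), dtype=int)
        cm = confusion(y, pooled_pred)
        confusions.append(cm)
        rows.append(metrics(cm))
    return EvaluationReport(confusions, rows, average_row(rows))
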