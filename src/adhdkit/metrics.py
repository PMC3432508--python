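"""Classifier evaluation: confusion counts, sensitivity/specificity,
Youden's J, F1, ROC curve, and AUC.

The positive class is ADHD throughout: sensitivity is the true-positive
rate on patients, specificity the true-negative rate on controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "confusion_counts",
    "sensitivity",
    "specificity",
    "j_statistic",
    "f1_score",
    "roc_curve",
    "auc",
    "evaluate_predictions",
]


@dataclass
class ConfusionCounts:
    tpos: int
    fneg: int
    fpos: int
    tneg: int

    def __post_init__(self) -> None:
        for name in ("tpos", "fneg", "fpos", "tneg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tpos + self.fneg + self.fpos + self.tneg


def confusion_counts(y_true, y_pred, positive_class) -> ConfusionCounts:
    """Exact binary confusion counts with an explicit positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    labels = set(np.unique(y_true)) | set(np.unique(y_pred))
    if len(labels) > 2:
        raise ValueError(f"labels are not binary: {sorted(map(str, labels))}")
    if positive_class not in labels:
        raise ValueError(f"unknown positive class {positive_class!r}; labels {sorted(map(str, labels))}")
    tp = y_true == positive_class
    pp = y_pred == positive_class
    return ConfusionCounts(
        tpos=int(np.sum(tp & pp)),
        fneg=int(np.sum(tp & ~pp)),
        fpos=int(np.sum(~tp & pp)),
        tneg=int(np.sum(~tp & ~pp)),
    )


def sensitivity(counts: ConfusionCounts) -> float:
    denom = counts.tpos + counts.fneg
    return counts.tpos / denom if denom else float("nan")


def specificity(counts: ConfusionCounts) -> float:
    denom = counts.tneg + counts.fpos
    return counts.tneg / denom if denom else float("nan")


def j_statistic(sens: float, spec: float) -> float:
    """Youden's J = sensitivity + specificity - 1, in [-1, 1]."""
    if not (0 <= sens <= 1 and 0 <= spec <= 1):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    return sens + spec - 1.0


def f1_score(counts: ConfusionCounts) -> float:
    """F1 = 2 TP / (2 TP + FN + FP); 0 (with a warning) when undefined."""
    denom = 2 * counts.tpos + counts.fneg + counts.fpos
    if denom == 0:
        warnings.warn("F1 undefined (no positives anywhere); returning 0", RuntimeWarning, stacklevel=2)
        return 0.0
    return 2.0 * counts.tpos / denom


def roc_curve(scores, y_true, positive_class) -> np.ndarray:
    """ROC points (1 - specificity, sensitivity), one per distinct decision
    threshold (scores descending), anchored at (0, 0) and ending at (1, 1)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    classes = np.unique(y_true)
    if classes.size < 2:
        raise ValueError("ROC requires both classes in y_true")
    fpr, tpr, _ = _sk_roc_curve(
        y_true, scores, pos_label=positive_class, drop_intermediate=False
    )
    return np.column_stack([fpr, tpr])


def auc(points: np.ndarray) -> float:
    """Trapezoidal area under an ROC curve (ties handled by the trapezoid
    through the tied block); equals P(score+ > score-) + 0.5 P(=)."""
    points = np.asarray(points, dtype=float)
    return float(np.trapezoid(points[:, 1], points[:, 0]))


@dataclass
class EvalReport:
    """Full reporting surface for one evaluated prediction set."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    j: float
    f1: float
    accuracy: float
    roc_points: np.ndarray | None = None
    auc: float | None = None
    per_fold: list["EvalReport"] = field(default_factory=list)

    def to_dict(self, ndigits: int = 4) -> dict:
        d = {
            "counts": {
                "tpos": self.counts.tpos,
                "fneg": self.counts.fneg,
                "fpos": self.counts.fpos,
                "tneg": self.counts.tneg,
            },
            "sensitivity": round(self.sensitivity, ndigits),
            "specificity": round(self.specificity, ndigits),
            "j_statistic": round(self.j, ndigits),
            "f1_score": round(self.f1, ndigits),
            "accuracy": round(self.accuracy, ndigits),
        }
        if self.auc is not None:
            d["auc"] = round(self.auc, ndigits)
        if self.per_fold:
            d["per_fold"] = [r.to_dict(ndigits) for r in self.per_fold]
        return d


def evaluate_predictions(
    y_true,
    y_pred,
    scores=None,
    positive_class="ADHD",
    fold_ids=None,
) -> EvalReport:
    """Build an :class:`EvalReport`; with ``fold_ids`` given, per-fold
    reports are attached alongside the pooled one."""
    counts = confusion_counts(y_true, y_pred, positive_class)
    sens = sensitivity(counts)
    spec = specificity(counts)
    report = EvalReport(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        j=j_statistic(sens, spec) if np.isfinite(sens) and np.isfinite(spec) else float("nan"),
        f1=f1_score(counts),
        accuracy=(counts.tpos + counts.tneg) / counts.total,
    )
    if scores is not None:
        points = roc_curve(scores, y_true, positive_class)
        report.roc_points = points
        report.auc = auc(points)
    if fold_ids is not None:
        fold_ids = np.asarray(fold_ids)
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        for f in np.unique(fold_ids):
            sel = fold_ids == f
            if np.unique(y_true[sel]).size < 2:
                continue  # single-class fold: rates undefined, skip
            report.per_fold.append(
                evaluate_predictions(
                    y_true[sel],
                    y_pred[sel],
                    None if scores is None else np.asarray(scores)[sel],
                    positive_class,
                )
            )
    return report
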