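"""Binary-classification metrics: SN, SP, ACC, MCC and the ROC curve.

Conventions: labels are +1 (positive class) and −1 (negative class);
metrics follow the standard confusion-matrix formulas

    SN  = TP / (TP + FN)            (sensitivity, recall on positives)
    SP  = TN / (TN + FP)            (specificity)
    ACC = (TP + TN) / total
    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A metric whose denominator is zero is *undefined* and raises
:class:`~acpsmo.errors.UndefinedMetricError`; it is never silently 0
(benchmark tables print a dash in that situation).  The ROC curve sweeps a
descending threshold over the scores, grouping tied scores into single
steps, and the AUC is the trapezoidal area — equivalently the
Mann–Whitney probability that a random positive outscores a random
negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must count at least one example")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class RocCurve:
    """Threshold-swept operating points: (FPR, TPR) from (0,0) to (1,1)."""

    points: np.ndarray
    auc: float


def confusion(predictions, truth) -> ConfusionMatrix:
    """Tally a confusion matrix from ±1 prediction and truth vectors."""
    pred = np.asarray(predictions)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    for arr, who in ((pred, "predictions"), (true, "truth")):
        if not np.isin(arr, (-1, 1)).all():
            raise ValueError(f"{who} must be +1/-1 labels")
    return ConfusionMatrix(
        tp=int(((pred == 1) & (true == 1)).sum()),
        tn=int(((pred == -1) & (true == -1)).sum()),
        fp=int(((pred == 1) & (true == -1)).sum()),
        fn=int(((pred == -1) & (true == 1)).sum()),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} is undefined: denominator is zero")
    return num / den


def sensitivity(cm: ConfusionMatrix) -> float:
    """SN = TP / (TP + FN)."""
    return _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")


def specificity(cm: ConfusionMatrix) -> float:
    """SP = TN / (TN + FP)."""
    return _ratio(cm.tn, cm.tn + cm.fp, "specificity")


def accuracy(cm: ConfusionMatrix) -> float:
    """ACC = (TP + TN) / (TP + TN + FP + FN)."""
    return _ratio(cm.tp + cm.tn, cm.total, "accuracy")


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient, in [−1, 1].

    Undefined (raises) when any marginal — predicted-positive,
    actual-positive, predicted-negative or actual-negative — is empty.
    """
    marginals = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if marginals == 0:
        raise UndefinedMetricError("mcc is undefined: a marginal count is zero")
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(marginals)


def metric_table(cm: ConfusionMatrix) -> dict[str, float]:
    """SN/SP/ACC/MCC in one dict (full precision; round for display)."""
    return {
        "SN": sensitivity(cm),
        "SP": specificity(cm),
        "ACC": accuracy(cm),
        "MCC": mcc(cm),
    }


def roc(scores, truth) -> RocCurve:
    """ROC curve and trapezoidal AUC from real-valued scores.

    Higher scores must indicate the positive class; tied scores move in a
    single diagonal step.  Requires both classes in `truth`.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth)
    if s.shape != y.shape:
        raise ValueError("scores and truth must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC requires both classes in the truth labels")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp = np.cumsum(y_sorted == 1)
    fp = np.cumsum(y_sorted == -1)
    # keep only the last index of each tied-score group
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted) != 0), len(s_sorted) - 1]
    tpr = np.r_[0.0, tp[distinct] / n_pos]
    fpr = np.r_[0.0, fp[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=np.column_stack([fpr, tpr]), auc=auc)
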