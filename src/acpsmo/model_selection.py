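"""Hyperparameter tuning: C/gamma grid search, posterior class-weight
sweep, and stratified ten-fold cross-validation.

The posterior weight is this pipeline's final tuning knob.  After Platt
calibration yields class probabilities (P⁺, P⁻), classification is redone
with a multiplier w swept over a grid (default 0.1 to 10 in steps of 0.1):

    positive  iff  w · P⁺ ≥ P⁻

which is algebraically the same as thresholding P⁺ at 1/(1+w).  The weight
that maximizes *training* accuracy is kept (smallest weight on ties) and
then applied unchanged to test data.  Sweeping w traces out the ROC curve
of the calibrated classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .errors import DataSizeError
from .evaluation import ConfusionMatrix, accuracy, confusion, metric_table
from .smo import (
    KernelSpec,
    SvmModel,
    TrainingProblem,
    calibrate,
    decision_values,
    predict_proba,
    train_smo,
)

#: The canonical coarse grids for the box constraint C and the rbf gamma.
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass(frozen=True)
class WeightGrid:
    """The posterior-weight sweep: lo, lo+step, ..., hi inclusive."""

    lo: float = 0.1
    hi: float = 10.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.lo <= 0 or self.hi < self.lo or self.step <= 0:
            raise ValueError("need 0 < lo <= hi and step > 0")

    def values(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.step)) + 1
        return np.round(self.lo + self.step * np.arange(n), 10)


@dataclass
class TunedModel:
    """A calibrated SVM plus its selected posterior weight and sweep report."""

    base: SvmModel
    weight: float
    training_report: list[tuple[float, float]] = field(default_factory=list)

    @property
    def kernel(self) -> KernelSpec:
        return self.base.kernel

    @property
    def C(self) -> float:
        return self.base.C

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return predict_proba(self.base, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return np.array(
            [weighted_classify(pp, pm, self.weight) for pp, pm in proba], dtype=int
        )


def weighted_classify(p_plus: float, p_minus: float, weight: float) -> int:
    """+1 iff weight·P⁺ ≥ P⁻, else −1.  Weight 1 is argmax with ties positive."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    return 1 if weight * p_plus >= p_minus else -1


def tune_weight(
    model: SvmModel,
    X: np.ndarray,
    y: np.ndarray,
    grid: Optional[WeightGrid] = None,
) -> TunedModel:
    """Sweep the posterior weight on training data; keep the accuracy maximizer.

    Every candidate's training accuracy is recorded in the returned
    `training_report`; ties go to the smallest weight.
    """
    grid = grid or WeightGrid()
    proba = predict_proba(model, X)
    y = np.asarray(y)
    report: list[tuple[float, float]] = []
    best_w, best_acc = None, -1.0
    for w in grid.values():
        pred = np.where(w * proba[:, 0] >= proba[:, 1], 1, -1)
        acc = float((pred == y).mean())
        report.append((float(w), acc))
        if acc > best_acc:  # strict: first (smallest) maximizer wins
            best_w, best_acc = float(w), acc
    return TunedModel(base=model, weight=best_w, training_report=report)


def stratified_folds(y: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    """Disjoint stratified folds; membership depends only on (labels, seed).

    Within each class, indices are shuffled and dealt round-robin, so fold
    sizes per class differ by at most one.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    for cls in (1, -1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < folds:
            raise DataSizeError(
                f"class {cls:+d} has {len(idx)} examples, fewer than {folds} folds; "
                "reduce the fold count"
            )
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return [np.flatnonzero(assignment == f) for f in range(folds)]


Trainer = Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]]


def make_smo_trainer(
    C: float = 1.0,
    kernel: Optional[KernelSpec] = None,
    seed: int = 0,
    weight: Optional[float] = None,
    weight_grid: Optional[WeightGrid] = None,
) -> Trainer:
    """A trainer closure: fit SMO + Platt (+ optional weight tuning).

    With `weight` set, classification uses that fixed posterior weight;
    with `weight_grid` set, the weight is tuned on each training split;
    otherwise the raw sign of the decision value is used.
    """
    kernel = kernel or KernelSpec()

    def fit(X: np.ndarray, y: np.ndarray) -> Callable[[np.ndarray], np.ndarray]:
        model = train_smo(TrainingProblem(X, y, C=C, kernel=kernel, seed=seed))
        if weight is None and weight_grid is None:
            return lambda Q: np.where(decision_values(model, Q) >= 0, 1, -1)
        model = calibrate(model)
        if weight_grid is not None:
            tuned = tune_weight(model, X, y, weight_grid)
        else:
            tuned = TunedModel(base=model, weight=weight)
        return tuned.predict

    return fit


@dataclass
class CvResult:
    """Per-fold and pooled cross-validation metrics."""

    fold_metrics: list[dict[str, Optional[float]]]
    pooled_confusion: ConfusionMatrix
    pooled: dict[str, float]
    fold_indices: list[np.ndarray]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    trainer: Trainer,
    folds: int = 10,
    seed: int = 0,
) -> CvResult:
    """Stratified k-fold cross-validation; every example is tested once.

    Per-fold SN/SP/ACC/MCC are reported (None where a fold leaves a metric
    undefined) together with the metrics of the pooled out-of-fold
    confusion matrix.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    fold_idx = stratified_folds(y, folds, seed)
    all_pred = np.empty(len(y), dtype=int)
    fold_metrics = []
    for test_idx in fold_idx:
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        predict = trainer(X[mask], y[mask])
        pred = np.asarray(predict(X[test_idx]))
        all_pred[test_idx] = pred
        cm = confusion(pred, y[test_idx])
        row: dict[str, Optional[float]] = {}
        for name in ("SN", "SP", "ACC", "MCC"):
            try:
                row[name] = metric_table(cm)[name]
            except Exception:
                row[name] = None
        fold_metrics.append(row)
    pooled_cm = confusion(all_pred, y)
    return CvResult(
        fold_metrics=fold_metrics,
        pooled_confusion=pooled_cm,
        pooled=metric_table(pooled_cm),
        fold_indices=fold_idx,
    )


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[Optional[float]] = (None,),
    kernel_kind: str = "linear",
    folds: int = 5,
    seed: int = 0,
) -> tuple[float, Optional[float], list[tuple[float, Optional[float], float]]]:
    """Pick (C, gamma) maximizing mean CV accuracy over a grid.

    For linear kernels pass ``gamma_grid=(None,)``.  Ties prefer smaller C,
    then smaller gamma.  Returns the winner plus the full score report
    as (C, gamma, mean_accuracy) rows.
    """
    if not len(C_grid) or not len(gamma_grid):
        raise ValueError("grids must be non-empty")
    if kernel_kind == "rbf" and any(g is None for g in gamma_grid):
        raise ValueError("rbf grid search requires numeric gamma values")
    report = []
    best = None
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid, key=lambda g: (g is not None, g)):
            kernel = KernelSpec(kernel_kind, gamma) if kernel_kind == "rbf" else KernelSpec("linear")
            res = cross_validate(
                X, y, make_smo_trainer(C=C, kernel=kernel, seed=seed), folds=folds, seed=seed
            )
            acc = res.pooled["ACC"]
            report.append((float(C), gamma, acc))
            if best is None or acc > best[2]:
                best = (float(C), gamma, acc)
    return best[0], best[1], report
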