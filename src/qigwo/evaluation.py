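"""Confusion-matrix metrics, ROC curves and stratified k-fold machinery.

Metrics follow the usual CAD conventions: accuracy, sensitivity and
specificity as percentages, Matthews correlation coefficient scaled to
[-100, 100].  Two error-rate conventions are reported side by side because
they disagree whenever the class mix is unbalanced:

``er_formula``
    1 - (SEN + SPC) / 200, the balanced-error form.
``er_complement``
    1 - ACC / 100, the plain misclassification rate.

Published mammography CAD tables frequently print the complement form while
quoting the balanced formula; exposing both avoids silently picking one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RocCurve",
    "compute_metrics",
    "confusion_from_predictions",
    "roc_curve",
    "stratified_kfold",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix cell counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Derived classification metrics; percentages except the error rates."""

    acc: float
    sen: float
    spc: float
    mcc: float
    er_formula: float
    er_complement: float
    mcc_degenerate: bool = False


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, sensitivity, specificity, MCC and both error rates.

    When any MCC denominator factor is zero (a degenerate margin) the MCC is
    reported as 0 with ``mcc_degenerate=True``.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = counts.total
    if total < 1:
        raise ValueError("confusion counts must cover at least one sample")

    acc = 100.0 * (tp + tn) / total
    sen = 100.0 * tp / (tp + fn) if tp + fn > 0 else 0.0
    spc = 100.0 * tn / (tn + fp) if tn + fp > 0 else 0.0

    denom_factors = [tp + fp, tp + fn, tn + fp, tn + fn]
    degenerate = any(f == 0 for f in denom_factors)
    if degenerate:
        mcc = 0.0
    else:
        # products in float to avoid integer overflow on large counts
        denom = np.sqrt(np.prod(np.array(denom_factors, dtype=float)))
        mcc = 100.0 * (tp * tn - fp * fn) / denom

    return MetricsReport(
        acc=acc,
        sen=sen,
        spc=spc,
        mcc=mcc,
        er_formula=1.0 - 0.5 * (sen + spc) / 100.0,
        er_complement=1.0 - acc / 100.0,
        mcc_degenerate=degenerate,
    )


def confusion_from_predictions(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """Tally binary confusion counts; label/prediction 1 is the positive class."""
    labels = np.asarray(labels).astype(int)
    predictions = np.asarray(predictions).astype(int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
        fn=int(np.sum((labels == 1) & (predictions == 0))),
    )


@dataclass(frozen=True)
class RocCurve:
    """ROC operating points (FPR, TPR) from (0,0) to (1,1) plus AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float = field(default=np.nan)


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve over descending score thresholds with trapezoidal AUC.

    Tied scores are grouped at a single threshold.  Requires both classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC curve undefined: labels contain a single class")
    fpr, tpr, thr = _skm.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def stratified_kfold(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seed-reproducible stratified fold assignment.

    Returns an integer array mapping each sample to a fold in [0, k).  Per
    class, fold sizes differ by at most one.  Classes smaller than ``k``
    are rejected.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    assignment = np.full(labels.shape[0], -1, dtype=int)
    start = 0  # rotate fold offsets across classes to balance fold totals
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls!r} has {idx.size} members, fewer than k={k} folds"
            )
        perm = rng.permutation(idx)
        assignment[perm] = (np.arange(perm.size) + start) % k
        start += perm.size
    return assignment
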