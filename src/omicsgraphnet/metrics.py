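"""The seven binary-classification metrics.

Cancer (label 1) is the positive class throughout: sensitivity is the
recall of cancer samples, specificity the recall of non-cancer samples.
Macro F1 averages the per-class F1 scores with equal weight; weighted
F1 weights them by class prevalence. AUC-ROC uses the rank (Mann-
Whitney) formulation with midranks for ties.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata

from .datatypes import ConfusionCounts, LabelVector, MetricsReport

__all__ = [
    "confusion",
    "precision",
    "sensitivity",
    "specificity",
    "accuracy",
    "f1_score",
    "macro_f1",
    "weighted_f1",
    "auc_roc",
    "evaluate_predictions",
]


def confusion(
    labels: LabelVector | np.ndarray, predicted: np.ndarray
) -> ConfusionCounts:
    """Count tp/fp/tn/fn with cancer (1) as the positive class."""
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    yhat = np.asarray(predicted)
    if y.shape != yhat.shape:
        raise ValueError(
            f"label vector has {y.size} entries, predictions {yhat.size}"
        )
    return ConfusionCounts(
        tp=int(((y == 1) & (yhat == 1)).sum()),
        fp=int(((y == 0) & (yhat == 1)).sum()),
        tn=int(((y == 0) & (yhat == 0)).sum()),
        fn=int(((y == 1) & (yhat == 0)).sum()),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(
            f"{name} undefined (zero denominator); returning 0", stacklevel=3
        )
        return 0.0
    return num / den


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp, "precision")


def sensitivity(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.tp + c.tn, c.total, "accuracy")


def f1_score(precision_: float, sensitivity_: float) -> float:
    """Harmonic mean of precision and sensitivity."""
    if precision_ + sensitivity_ == 0:
        return 0.0
    return 2 * precision_ * sensitivity_ / (precision_ + sensitivity_)


def _per_class_f1(c: ConfusionCounts) -> tuple[float, float]:
    """(F1 of the positive class, F1 of the negative class).

    The negative-class F1 swaps the roles: tn become "true positives"
    of the non-cancer class, fn its false positives.
    """
    f1_pos = f1_score(precision(c), sensitivity(c))
    c_neg = ConfusionCounts(tp=c.tn, fp=c.fn, tn=c.tp, fn=c.fp)
    f1_neg = f1_score(precision(c_neg), sensitivity(c_neg))
    return f1_pos, f1_neg


def macro_f1(c: ConfusionCounts) -> float:
    """Unweighted mean of the per-class F1 scores."""
    f1_pos, f1_neg = _per_class_f1(c)
    return (f1_pos + f1_neg) / 2.0


def weighted_f1(c: ConfusionCounts, variant: str = "standard") -> float:
    """Class-prevalence-weighted mean of the per-class F1 scores.

    ``variant="standard"`` divides by the total sample count, the usual
    definition bounded by 1. ``variant="as_printed"`` divides the
    count-weighted sum by 2 instead; that quantity exceeds 1 whenever
    n > 2 and is provided only for comparability, with a warning.
    """
    f1_pos, f1_neg = _per_class_f1(c)
    n_pos = c.tp + c.fn
    n_neg = c.tn + c.fp
    weighted_sum = n_pos * f1_pos + n_neg * f1_neg
    if variant == "standard":
        if n_pos + n_neg == 0:
            return 0.0
        return weighted_sum / (n_pos + n_neg)
    if variant == "as_printed":
        warnings.warn(
            "'as_printed' weighted F1 divides the count-weighted sum by 2 "
            "and is unbounded above 1; use 'standard' for a [0, 1] metric",
            stacklevel=2,
        )
        return weighted_sum / 2.0
    raise ValueError(f"unknown weighted_f1 variant {variant!r}")


def auc_roc(labels: LabelVector | np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC-ROC (Mann-Whitney with midranks for ties)."""
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)
    s = np.asarray(scores, float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC-ROC requires both classes present")
    ranks = rankdata(s)
    rank_sum_pos = ranks[y == 1].sum()
    return float(
        (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def evaluate_predictions(
    labels: LabelVector | np.ndarray,
    predicted: np.ndarray,
    scores: np.ndarray,
    metadata: dict | None = None,
) -> MetricsReport:
    """Assemble the full seven-metric report for one evaluation."""
    c = confusion(labels, predicted)
    return MetricsReport(
        sensitivity=sensitivity(c),
        specificity=specificity(c),
        accuracy=accuracy(c),
        precision=precision(c),
        auc_roc=auc_roc(labels, scores),
        macro_f1=macro_f1(c),
        weighted_f1=weighted_f1(c),
        confusion=c,
        metadata=metadata or {},
    )
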