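"""Evaluation statistics for classifiers and feature-recovery experiments.

Two balanced-accuracy variants are exposed.  :func:`balanced_accuracy`
divides each diagonal confusion count by the *larger* of its row or column
sum before averaging over classes; it penalizes both missed and spurious
predictions for a class and is the score used throughout the benchmark
harness.  :func:`mean_recall_accuracy` is the common mean-per-class-recall
definition (scikit-learn's ``balanced_accuracy_score``); the two coincide
whenever the confusion matrix has matching row and column sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import balanced_accuracy_score as _sk_mean_recall

__all__ = [
    "ConfusionMatrix",
    "balanced_accuracy",
    "balanced_accuracy_from_labels",
    "mean_recall_accuracy",
    "FeatureRecoveryCounts",
    "mcc_feature_recovery",
    "cohen_kappa",
    "KappaErrorPoint",
    "kappa_error_points",
    "spearman_rank_consistency",
    "jaccard_distance",
]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    classes: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, y_true, y_pred, classes=None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have equal length")
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)))
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, classes=list(classes))


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean over classes of c_ii / max(row sum, column sum).

    Classes with zero row *and* column sum do not count towards the mean.
    """
    c = cm.counts
    if c.sum() == 0:
        raise ValueError("empty confusion matrix")
    rows = c.sum(axis=1)
    cols = c.sum(axis=0)
    active = (rows + cols) > 0
    denom = np.maximum(rows[active], cols[active])
    return float(np.mean(np.diag(c)[active] / denom))


def balanced_accuracy_from_labels(y_true, y_pred, classes=None) -> float:
    return balanced_accuracy(ConfusionMatrix.from_labels(y_true, y_pred, classes))


def mean_recall_accuracy(y_true, y_pred) -> float:
    """The common mean-per-class-recall balanced accuracy."""
    return float(_sk_mean_recall(y_true, y_pred))


# ----------------------------------------------------------------------
@dataclass
class FeatureRecoveryCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @classmethod
    def from_sets(cls, selected, truth, universe_size: int) -> "FeatureRecoveryCounts":
        selected, truth = set(selected), set(truth)
        if len(selected | truth) > universe_size:
            raise ValueError("selected/truth exceed the feature universe")
        tp = len(selected & truth)
        fp = len(selected - truth)
        fn = len(truth - selected)
        tn = universe_size - tp - fp - fn
        return cls(tp=tp, fp=fp, fn=fn, tn=tn)


def mcc_feature_recovery(selected, truth, universe_size: int) -> float:
    """Matthews correlation between a selected feature set and the planted truth.

    A zero factor in the denominator yields 0 (the dominant convention).
    """
    c = FeatureRecoveryCounts.from_sets(selected, truth, universe_size)
    num = c.tp * c.tn - c.fp * c.fn
    den = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if den == 0:
        return 0.0
    return float(num / np.sqrt(den))


# ----------------------------------------------------------------------
def cohen_kappa(pred_a, pred_b) -> float:
    """Cohen's kappa between two label vectors.

    When the chance agreement p_e is 1 (both raters constant), kappa is
    defined as 1 if the raters agree exactly and 0 otherwise.
    """
    a = np.asarray(pred_a)
    b = np.asarray(pred_b)
    if a.shape != b.shape:
        raise ValueError("prediction vectors must have equal length")
    n = a.size
    classes = sorted(set(a) | set(b))
    po = float(np.mean(a == b))
    pe = sum(np.mean(a == c) * np.mean(b == c) for c in classes)
    if pe >= 1.0 - 1e-15:
        return 1.0 if po >= 1.0 - 1e-15 else 0.0
    return float((po - pe) / (1.0 - pe))


@dataclass
class KappaErrorPoint:
    """One tree pair: agreement (kappa) vs mean of the two error rates."""

    kappa: float
    mean_pair_error: float
    pair: tuple[int, int]


def kappa_error_points(ensemble, X, y) -> list[KappaErrorPoint]:
    """Kappa-error diagram coordinates for every unordered tree pair.

    ``ensemble`` must expose ``trees_`` where each tree predicts hard labels.
    """
    y = np.asarray(y)
    preds = [np.asarray(t.predict(X)) for t in ensemble.trees_]
    errors = [float(np.mean(p != y)) for p in preds]
    points = []
    for i, j in combinations(range(len(preds)), 2):
        points.append(
            KappaErrorPoint(
                kappa=cohen_kappa(preds[i], preds[j]),
                mean_pair_error=(errors[i] + errors[j]) / 2.0,
                pair=(i, j),
            )
        )
    return points


# ----------------------------------------------------------------------
def spearman_rank_consistency(importance_a, importance_b) -> float:
    """Spearman's rho between two feature-importance vectors (average ranks
    for ties).  Eliminated features must already carry importance 0."""
    a = np.asarray(importance_a, dtype=float)
    b = np.asarray(importance_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("importance vectors must be aligned")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho = spearmanr(a, b).statistic
    return float(rho)


def jaccard_distance(set_a, set_b) -> float:
    """1 - |A∩B| / |A∪B|; two empty sets are identical (distance 0)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)
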