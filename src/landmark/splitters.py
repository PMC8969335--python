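"""Candidate node models for oblique decision trees.

At every tree node a pool of multivariate classifiers competes to become the
splitting rule: L2/L1 logistic regression, a linear SVM, two stochastic
gradient descent linear models (L2 and elastic-net penalties), ridge
regression, and — at large nodes — a neural network.  Each model partitions
the node's samples by its predicted class, so a fitted model *is* an oblique
(or curved) split.

Tuning rules: nodes with more than 6 samples run a small stratified
cross-validated grid search for the regularization strength (and, for SGD,
the loss); at 6 samples or fewer fixed defaults are used (C/alpha = 1, SGD
loss picked at random).  Ridge tunes itself by generalized cross-validation
and is skipped entirely at tiny nodes.  The neural model only competes when
more than 32 samples enter the node.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn import config_context as sklearn_config
from sklearn.base import clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import (
    LogisticRegression,
    LogisticRegressionCV,
    RidgeClassifierCV,
    SGDClassifier,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC


def _mean_recall(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean per-class recall on integer-coded labels (CV scorer)."""
    recalls = []
    for c in np.unique(y_true):
        mask = y_true == c
        recalls.append(np.mean(y_pred[mask] == c))
    return float(np.mean(recalls))

logger = logging.getLogger(__name__)

__all__ = [
    "SplitterSpec",
    "RegularizationParams",
    "FittedSplitter",
    "DEFAULT_SPECS",
    "select_hyperparameters",
    "fit_linear_splitter",
]

LOGISTIC_C_GRID = np.logspace(-4, 4, 10)
SVC_SGD_GRID = np.array([0.001, 0.01, 0.1, 1.0, 10.0, 100.0])
RIDGE_ALPHA_GRID = np.logspace(-3, 4, 20)
SGD_LOSSES = ("hinge", "modified_huber")
MAX_ITER = 2000

LINEAR_FAMILIES = (
    "logistic_l2",
    "logistic_l1",
    "linear_svc",
    "sgd_l2",
    "sgd_elasticnet",
    "ridge",
)


@dataclass(frozen=True)
class SplitterSpec:
    """Configuration of one candidate node model."""

    family: str
    uses_random_feature_subset: bool
    min_samples_to_fit: int = 2
    min_samples_to_tune: int = 7
    hyperparameter_grid: dict = field(default_factory=dict)


def default_specs() -> list[SplitterSpec]:
    """The candidate pool: six linear configurations plus the neural model."""
    return [
        SplitterSpec("logistic_l2", True, hyperparameter_grid={"C": list(LOGISTIC_C_GRID)}),
        SplitterSpec("logistic_l1", False, hyperparameter_grid={"C": list(LOGISTIC_C_GRID)}),
        SplitterSpec("linear_svc", True, hyperparameter_grid={"C": list(SVC_SGD_GRID)}),
        SplitterSpec(
            "sgd_l2", True,
            hyperparameter_grid={"alpha": list(SVC_SGD_GRID), "loss": list(SGD_LOSSES)},
        ),
        SplitterSpec(
            "sgd_elasticnet", False,
            hyperparameter_grid={"alpha": list(SVC_SGD_GRID), "loss": list(SGD_LOSSES)},
        ),
        # ridge regression self-tunes by GCV and is unavailable at nodes <= 6 samples
        SplitterSpec("ridge", True, min_samples_to_fit=7),
        SplitterSpec("neural_net", True, min_samples_to_fit=33),
    ]


DEFAULT_SPECS = default_specs()


@dataclass
class RegularizationParams:
    C: float | None = None
    alpha: float | None = None
    loss: str | None = None


@dataclass
class FittedSplitter:
    """A fitted node model plus the feature subset it reads.

    ``partition(X)`` maps samples to branch labels — the model's predicted
    class labels, or {"left", "right"} for the random oracle.
    """

    family: str
    model: Any
    feature_subset: np.ndarray | None = None  # None = full feature set
    gain: float = 0.0

    def partition(self, X: np.ndarray) -> np.ndarray:
        Xs = X if self.feature_subset is None else X[:, self.feature_subset]
        return np.asarray(self.model.predict(Xs))

    # -- persistence ---------------------------------------------------
    def to_dict(self) -> dict:
        d: dict[str, Any] = {"family": self.family, "gain": self.gain}
        d["feature_subset"] = (
            None if self.feature_subset is None else [int(i) for i in self.feature_subset]
        )
        m = self.model
        if hasattr(m, "to_dict"):  # neural / oracle / deserialized linear
            d["model"] = m.to_dict()
        else:
            d["model"] = {
                "kind": "linear",
                "coef": np.atleast_2d(m.coef_).tolist(),
                "intercept": np.atleast_1d(m.intercept_).tolist(),
                "classes": [str(c) for c in m.classes_],
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FittedSplitter":
        model_d = d["model"]
        kind = model_d.get("kind", "linear")
        if kind == "linear":
            model: Any = LinearDecision(
                coef=np.asarray(model_d["coef"], dtype=float),
                intercept=np.asarray(model_d["intercept"], dtype=float),
                classes=np.asarray(model_d["classes"]),
            )
        elif kind == "oracle":
            from .tree import OracleHyperplane

            model = OracleHyperplane.from_dict(model_d)
        elif kind == "neural":
            from .neural import NeuralSplitter

            model = NeuralSplitter.from_dict(model_d)
        else:
            raise ValueError(f"unknown splitter kind {kind!r}")
        subset = d.get("feature_subset")
        return cls(
            family=d["family"],
            model=model,
            feature_subset=None if subset is None else np.asarray(subset, dtype=int),
            gain=float(d.get("gain", 0.0)),
        )


@dataclass
class LinearDecision:
    """Minimal linear decision function reconstructed from serialized weights."""

    coef: np.ndarray
    intercept: np.ndarray
    classes: np.ndarray

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef.T + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        if scores.shape[1] == 1:  # binary: positive score -> second class
            idx = (scores[:, 0] > 0).astype(int)
        else:
            idx = np.argmax(scores, axis=1)
        return self.classes[idx]

    def to_dict(self) -> dict:
        return {
            "kind": "linear",
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "classes": [str(c) for c in self.classes],
        }


# ----------------------------------------------------------------------
def _make_estimator(family: str, params: RegularizationParams, seed: int):
    if family == "logistic_l2":
        return LogisticRegression(
            l1_ratio=0.0, solver="lbfgs", max_iter=MAX_ITER, C=params.C or 1.0
        )
    if family == "logistic_l1":
        return LogisticRegression(
            l1_ratio=1.0, solver="liblinear", max_iter=MAX_ITER, C=params.C or 1.0,
            random_state=seed,
        )
    if family == "linear_svc":
        return LinearSVC(max_iter=MAX_ITER, C=params.C or 1.0)
    if family in ("sgd_l2", "sgd_elasticnet"):
        return SGDClassifier(
            loss=params.loss or "hinge",
            penalty="l2" if family == "sgd_l2" else "elasticnet",
            alpha=params.alpha if params.alpha is not None else 1.0,
            max_iter=MAX_ITER,
            random_state=seed,
        )
    if family == "ridge":
        return RidgeClassifierCV(alphas=RIDGE_ALPHA_GRID)
    raise ValueError(f"unknown linear family {family!r}")


def _grid_candidates(spec: SplitterSpec) -> list[RegularizationParams]:
    grid = spec.hyperparameter_grid
    if spec.family.startswith("logistic"):
        return [RegularizationParams(C=float(c)) for c in grid.get("C", LOGISTIC_C_GRID)]
    if spec.family == "linear_svc":
        return [RegularizationParams(C=float(c)) for c in grid.get("C", SVC_SGD_GRID)]
    if spec.family.startswith("sgd"):
        alphas = grid.get("alpha", SVC_SGD_GRID)
        losses = grid.get("loss", SGD_LOSSES)
        return [
            RegularizationParams(alpha=float(a), loss=str(l))
            for a in alphas
            for l in losses
        ]
    return [RegularizationParams()]


def select_hyperparameters(
    spec: SplitterSpec,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> RegularizationParams:
    """Choose regularization by stratified cross-validated grid search.

    Nodes of 6 or fewer samples skip the search: C/alpha default to 1.0 and
    the SGD loss is chosen uniformly at random.  The fold count shrinks from
    5 down to the smallest class size; below 2 usable folds the defaults are
    returned.  Ties break towards the first grid value.
    """
    y = np.asarray(y)
    defaults = RegularizationParams(
        C=1.0,
        alpha=1.0,
        loss=str(rng.choice(SGD_LOSSES)) if spec.family.startswith("sgd") else None,
    )
    if spec.family == "ridge":
        return RegularizationParams()  # GCV happens inside RidgeClassifierCV.fit
    if len(y) < spec.min_samples_to_tune:
        return defaults
    _, counts = np.unique(y, return_counts=True)
    n_folds = int(min(5, counts.min()))
    if n_folds < 2:
        return defaults
    cv = StratifiedKFold(n_splits=n_folds, shuffle=False)
    seed = int(rng.integers(2**31 - 1))
    # integer-encoded labels and a local mean-recall scorer keep the per-fit
    # overhead tolerable: the grid runs at every tree node
    _, y_codes = np.unique(y, return_inverse=True)
    folds = list(cv.split(X, y_codes))
    with warnings.catch_warnings(), sklearn_config(
        assume_finite=True, skip_parameter_validation=True
    ):
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", FutureWarning)
        if spec.family.startswith("logistic"):
            # warm-started regularization path: same grid/CV/scoring as an
            # explicit per-C loop, orders of magnitude less overhead
            grid = np.asarray(
                spec.hyperparameter_grid.get("C", LOGISTIC_C_GRID), dtype=float
            )
            path = LogisticRegressionCV(
                Cs=grid,
                cv=folds,
                scoring="balanced_accuracy",
                solver="lbfgs" if spec.family == "logistic_l2" else "liblinear",
                l1_ratios=[0.0] if spec.family == "logistic_l2" else [1.0],
                max_iter=MAX_ITER,
                random_state=seed,
            )
            path.fit(X, y_codes)
            # ties resolve to the first (smallest) grid value, as argmax would
            mean_scores = list(path.scores_.values())[0].mean(axis=0).ravel()
            return RegularizationParams(C=float(grid[int(np.argmax(mean_scores))]))
        candidates = _grid_candidates(spec)
        scores = np.zeros(len(candidates))
        for k, params in enumerate(candidates):
            est = _make_estimator(spec.family, params, seed)
            fold_scores = []
            for tr, va in folds:
                m = clone(est)
                m.fit(X[tr], y_codes[tr])
                fold_scores.append(_mean_recall(y_codes[va], m.predict(X[va])))
            scores[k] = np.mean(fold_scores)
    best = candidates[int(np.argmax(scores))]  # argmax keeps the first maximum
    if best.loss is None and spec.family.startswith("sgd"):
        best.loss = defaults.loss
    return best


def fit_linear_splitter(
    spec: SplitterSpec,
    X: np.ndarray,
    y: np.ndarray,
    feature_subset: np.ndarray | None,
    params: RegularizationParams,
    rng: np.random.Generator,
    bootstrap: bool = True,
) -> FittedSplitter:
    """Fit one linear candidate on (optionally) a bootstrap resample.

    The model is trained on a bootstrap resample of the node's samples but
    its information gain is later judged on the full node, which decorrelates
    candidate rules across trees.  If the resample collapses to one class the
    full node is used instead.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("cannot fit a splitter on a single-class node")
    if spec.family == "ridge" and len(y) < spec.min_samples_to_fit:
        raise ValueError("ridge splitter unavailable at nodes of <= 6 samples")
    Xs = X if feature_subset is None else X[:, feature_subset]
    Xfit, yfit = Xs, y
    if bootstrap:
        idx = rng.integers(0, len(y), size=len(y))
        if len(np.unique(y[idx])) >= 2:
            Xfit, yfit = Xs[idx], y[idx]
    seed = int(rng.integers(2**31 - 1))
    est = _make_estimator(spec.family, params, seed)
    with warnings.catch_warnings(record=True) as caught, sklearn_config(
        assume_finite=True, skip_parameter_validation=True
    ):
        warnings.simplefilter("always", ConvergenceWarning)
        est.fit(Xfit, yfit)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            logger.debug("%s splitter did not converge within %d iterations; "
                         "using fitted state as-is", spec.family, MAX_ITER)
            break
    return FittedSplitter(family=spec.family, model=est, feature_subset=feature_subset)
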