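"""Downstream biomarker-selection experiments.

Recursive feature elimination (RFE) to a fixed-size marker panel, Shapley or
model-native importances, the half-split rank-consistency experiment (how
stably does a model order features when the sample space is perturbed?), and
a multi-model benchmark harness emitting tidy result tables for external
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import (
    LogisticRegressionCV,
    RidgeClassifierCV,
    SGDClassifier,
)
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.svm import LinearSVC

from .ensemble import LANDMarkClassifier
from .metrics import (
    balanced_accuracy_from_labels,
    jaccard_distance,
    mcc_feature_recovery,
    spearman_rank_consistency,
)
from .shapley import ImportanceVector, shapley_importance
from .table import FeatureTable, LabelVector

__all__ = [
    "SelectionResult",
    "ConsistencyResult",
    "model_importances",
    "rfe_select",
    "half_split_consistency_experiment",
    "run_benchmark",
    "default_model_factories",
]

_REG_GRID = np.logspace(-4, 4, 20)


def default_model_factories(random_state: int | None = None, landmark_kwargs=None) -> dict:
    """The benchmark model zoo: the oblique ensembles plus the standard
    comparison classifiers at (near-)default settings, with cross-validated
    regularization for the linear models."""
    lk = dict(landmark_kwargs or {})

    def _sgd(loss):
        return lambda seed=random_state: GridSearchCV(
            SGDClassifier(loss=loss, random_state=seed),
            {"alpha": _REG_GRID},
            cv=5,
        )

    return {
        "LANDMark (Oracle)": lambda seed=random_state: LANDMarkClassifier(
            use_oracle=True, random_state=seed, **lk
        ),
        "LANDMark (No Oracle)": lambda seed=random_state: LANDMarkClassifier(
            use_oracle=False, random_state=seed, **lk
        ),
        "Extra Trees": lambda seed=random_state: ExtraTreesClassifier(random_state=seed),
        "Random Forest": lambda seed=random_state: RandomForestClassifier(random_state=seed),
        "Linear SVC": lambda seed=random_state: GridSearchCV(
            LinearSVC(), {"C": _REG_GRID}, cv=5
        ),
        "Logistic Regression": lambda seed=random_state: LogisticRegressionCV(
            Cs=_REG_GRID, max_iter=2000
        ),
        "Ridge Regression": lambda seed=random_state: RidgeClassifierCV(
            alphas=np.logspace(-3, 4, 20)
        ),
        "SGD (MH)": _sgd("modified_huber"),
        "SGD (SH)": _sgd("squared_hinge"),
    }


def model_importances(model) -> np.ndarray:
    """Non-negative per-feature scores from a fitted model: impurity/gain
    importances when available, else mean |coefficient| over classes."""
    if isinstance(model, GridSearchCV):
        model = model.best_estimator_
    imp = getattr(model, "feature_importances_", None)
    if imp is not None:
        return np.asarray(imp, dtype=float)
    coef = getattr(model, "coef_", None)
    if coef is not None:
        return np.abs(np.atleast_2d(coef)).mean(axis=0)
    raise ValueError(
        f"{type(model).__name__} exposes neither feature_importances_ nor coef_"
    )


# ----------------------------------------------------------------------
@dataclass
class SelectionResult:
    """Outcome of one RFE run.

    ``elimination_order`` lists feature indices from first-eliminated (least
    important) to last; the surviving panel is appended in ascending final
    importance, so reversing the list ranks features best-first.
    """

    selected: list
    elimination_order: list
    importances: np.ndarray
    feature_ids: list | None = None
    model_name: str | None = None
    seed: int | None = None


def rfe_select(
    model_factory,
    X: np.ndarray,
    y,
    n_keep: int = 100,
    step_fraction: float = 0.1,
    rng: np.random.Generator | int | None = None,
    feature_ids=None,
    importance_fn=model_importances,
) -> SelectionResult:
    """Recursive feature elimination down to an ``n_keep``-feature panel.

    Iteratively fits ``model_factory()``, scores features with
    ``importance_fn`` and drops the lowest ``ceil(step_fraction * remaining)``
    (never crossing below ``n_keep``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    d = X.shape[1]
    if n_keep >= d:
        raise ValueError(f"n_keep={n_keep} must be smaller than {d} features")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    remaining = np.arange(d)
    eliminated: list[int] = []
    final_imp = np.zeros(d)
    while True:
        model = model_factory()
        if hasattr(model, "random_state") and model.random_state is None:
            model.random_state = int(rng.integers(2**31 - 1))
        model.fit(X[:, remaining], y)
        imp = importance_fn(model)
        if imp.shape[0] != remaining.size:
            raise ValueError("importance vector does not match the feature count")
        final_imp[:] = 0.0
        final_imp[remaining] = imp
        if remaining.size == n_keep:
            break
        n_drop = min(
            int(np.ceil(step_fraction * remaining.size)), remaining.size - n_keep
        )
        order = np.argsort(imp, kind="stable")  # ascending: worst first
        drop = order[:n_drop]
        eliminated.extend(int(i) for i in remaining[drop])
        remaining = np.delete(remaining, drop)

    survivors = remaining[np.argsort(final_imp[remaining], kind="stable")]
    elimination_order = eliminated + [int(i) for i in survivors]
    selected = sorted(int(i) for i in remaining)
    if feature_ids is not None:
        selected = [feature_ids[i] for i in selected]
        elimination_order = [feature_ids[i] for i in elimination_order]
    return SelectionResult(
        selected=selected,
        elimination_order=elimination_order,
        importances=final_imp,
        feature_ids=list(feature_ids) if feature_ids is not None else None,
    )


# ----------------------------------------------------------------------
@dataclass
class ConsistencyResult:
    """Tidy per-repeat records plus the rank-consistency summaries."""

    records: pd.DataFrame
    rho: dict = field(default_factory=dict)  # model -> list of per-repeat rho
    jaccard: dict = field(default_factory=dict)  # model -> list of per-repeat distances

    def summary(self) -> pd.DataFrame:
        rows = []
        for model, rhos in self.rho.items():
            rows.append(
                {
                    "model": model,
                    "mean_rho": float(np.mean(rhos)),
                    "sd_rho": float(np.std(rhos, ddof=1)) if len(rhos) > 1 else np.nan,
                    "mean_jaccard_distance": float(np.mean(self.jaccard[model])),
                }
            )
        return pd.DataFrame(rows)


def half_split_consistency_experiment(
    table: FeatureTable | np.ndarray,
    labels: LabelVector | np.ndarray,
    model_factories: dict,
    n_repeats: int = 30,
    n_keep: int = 100,
    step_fraction: float = 0.1,
    use_shapley: bool = False,
    n_coalition_samples: int = 768,
) -> ConsistencyResult:
    """Perturb the sample space by stratified halving and measure how
    consistently each model ranks and selects features.

    Per repeat (split seeded with the iteration number): fit a full model on
    each half and score it on the opposite half; run RFE per half; fit and
    score the reduced models; build per-half importance vectors over all
    features (eliminated features score exactly 0 — with ``use_shapley`` the
    panel is re-scored by kernel Shapley sampling, otherwise by the model's
    native importances); record Spearman's rho between the halves' ranks and
    the Jaccard distance between the selected panels.
    """
    if isinstance(table, FeatureTable):
        X, feature_ids = table.values, table.feature_ids
    else:
        X = np.asarray(table, dtype=float)
        feature_ids = list(range(X.shape[1]))
    y = labels.labels if isinstance(labels, LabelVector) else np.asarray(labels)

    counts = pd.Series(y).value_counts()
    if counts.min() < 4:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} samples; halving needs >= 4"
        )

    rows = []
    rho: dict[str, list] = {m: [] for m in model_factories}
    jac: dict[str, list] = {m: [] for m in model_factories}
    all_idx = np.arange(X.shape[0])
    for rep in range(n_repeats):
        half_a, half_b = train_test_split(
            all_idx, test_size=0.5, stratify=y, random_state=rep
        )
        for name, factory in model_factories.items():
            imps, panels = [], []
            for me, other in ((half_a, half_b), (half_b, half_a)):
                full = factory()
                full.fit(X[me], y[me])
                full_score = balanced_accuracy_from_labels(y[other], full.predict(X[other]))
                sel = rfe_select(
                    factory, X[me], y[me], n_keep=n_keep,
                    step_fraction=step_fraction, rng=rep,
                )
                cols = np.asarray(sorted(sel.selected))
                reduced = factory()
                reduced.fit(X[me][:, cols], y[me])
                red_score = balanced_accuracy_from_labels(
                    y[other], reduced.predict(X[other][:, cols])
                )
                imp = np.zeros(X.shape[1])
                if use_shapley:
                    iv = shapley_importance(
                        reduced, X[me][:, cols], X[me][:, cols],
                        n_coalition_samples=n_coalition_samples, rng=rep,
                    )
                    imp[cols] = iv.scores
                else:
                    imp[cols] = model_importances(reduced)
                imps.append(imp)
                panels.append(set(cols.tolist()))
                rows.append(
                    {
                        "repeat": rep, "model": name,
                        "score_full": full_score, "score_reduced": red_score,
                    }
                )
            r = spearman_rank_consistency(imps[0], imps[1])
            rho[name].append(r)
            jd = jaccard_distance(panels[0], panels[1])
            jac[name].append(jd)
            for row in rows[-2:]:
                row["rho"] = r
                row["jaccard_distance"] = jd
    return ConsistencyResult(records=pd.DataFrame(rows), rho=rho, jaccard=jac)


# ----------------------------------------------------------------------
def run_benchmark(
    datasets: dict,
    model_factories: dict,
    n_repeats: int = 30,
    test_fraction: float = 0.2,
) -> pd.DataFrame:
    """Repeated stratified train/test benchmark over datasets and models.

    ``datasets`` maps a name to ``(X, y)`` or ``(X, y, truth_indices)``; when
    truth indices are present the top-|truth| features (by the fitted
    model's importances) are additionally scored by feature-recovery MCC.
    Split *i* uses random state *i*.  Per-cell failures are recorded and the
    run continues.

    Returns a tidy frame: dataset, model, repeat, metric, value.
    """
    rows = []
    for ds_name, payload in datasets.items():
        X, y = np.asarray(payload[0], dtype=float), np.asarray(payload[1])
        truth = set(payload[2]) if len(payload) > 2 else None
        for rep in range(n_repeats):
            tr, te = train_test_split(
                np.arange(X.shape[0]), test_size=test_fraction,
                stratify=y, random_state=rep,
            )
            for name, factory in model_factories.items():
                try:
                    model = factory()
                    if hasattr(model, "random_state") and model.random_state is None:
                        model.random_state = rep
                    model.fit(X[tr], y[tr])
                    score = balanced_accuracy_from_labels(y[te], model.predict(X[te]))
                    rows.append(
                        dict(dataset=ds_name, model=name, repeat=rep,
                             metric="balanced_accuracy", value=score)
                    )
                    if truth is not None:
                        imp = model_importances(model)
                        top = np.argsort(-imp, kind="stable")[: len(truth)]
                        mcc = mcc_feature_recovery(
                            set(int(i) for i in top), truth, X.shape[1]
                        )
                        rows.append(
                            dict(dataset=ds_name, model=name, repeat=rep,
                                 metric="feature_mcc", value=mcc)
                        )
                except Exception as exc:  # record and continue
                    rows.append(
                        dict(dataset=ds_name, model=name, repeat=rep,
                             metric="error", value=np.nan, note=str(exc))
                    )
    return pd.DataFrame(rows)
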