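"""Forest of oblique trees, plus decision-space geometry diagnostics.

The classifier averages per-tree leaf class distributions.  Decision-space
diagnostics come from the terminal-leaf proximity matrix: ``p(i, j)`` is the
fraction of trees in which samples *i* and *j* share a leaf, turned into a
dissimilarity by ``sqrt(1 - p)`` and visualized by classical principal
coordinates analysis (PCoA).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .tree import LANDMarkTree, TreeParams, build_tree

__all__ = [
    "LANDMarkClassifier",
    "ProximityMatrix",
    "PCoAResult",
    "proximity_to_dissimilarity",
    "pcoa",
]


@dataclass
class ProximityMatrix:
    """Symmetric co-occurrence frequencies in [0, 1]; diagonal is 1."""

    values: np.ndarray
    sample_ids: list | None = None


@dataclass
class PCoAResult:
    coordinates: np.ndarray
    explained_variance_ratio: np.ndarray
    eigenvalues: np.ndarray


def proximity_to_dissimilarity(prox: ProximityMatrix | np.ndarray) -> np.ndarray:
    """d(i, j) = sqrt(1 - p(i, j)); the diagonal is exactly zero."""
    p = prox.values if isinstance(prox, ProximityMatrix) else np.asarray(prox)
    d = np.sqrt(np.clip(1.0 - p, 0.0, None))
    np.fill_diagonal(d, 0.0)
    return d


def pcoa(dissimilarity: np.ndarray, n_axes: int | None = None) -> PCoAResult:
    """Classical scaling: double-center -D²/2, eigendecompose, keep the
    positive-eigenvalue axes.  Explained ratios are over positive eigenvalues
    only (negative eigenvalues from non-Euclidean dissimilarities are
    dropped, no Lingoes/Cailliez correction)."""
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-10):
        raise ValueError("dissimilarity must have a zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(1e-12, 1e-12 * abs(eigval[0]))
    if not np.any(pos):
        raise ValueError("degenerate dissimilarity: no positive eigenvalues")
    eigval_pos = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(eigval_pos)
    ratios = eigval_pos / eigval_pos.sum()
    if n_axes is not None:
        coords = coords[:, :n_axes]
        ratios = ratios[:n_axes]
        eigval_pos = eigval_pos[:n_axes]
    return PCoAResult(
        coordinates=coords,
        explained_variance_ratio=ratios,
        eigenvalues=eigval_pos,
    )


class LANDMarkClassifier:
    """Bagged ensemble of trees with learned multivariate node splits.

    Parameters
    ----------
    n_estimators : int
        Number of trees (64 by default).
    use_oracle : bool
        Offer a random linear oracle (hyperplane through the midpoint of two
        randomly chosen training samples) in the candidate pool.
    oracle_mode : {"candidate", "root"}
        "candidate" (default) lets the oracle compete on information gain at
        every node; "root" pre-partitions each tree's root with it
        unconditionally (the classic random-linear-oracle ensemble design).
    max_features_fraction : float or "sqrt"
        Features considered by subset-using node models, as a fraction of the
        total (0.4 by default — generalization tends to plateau there) or the
        square root of the feature count.
    bootstrap : bool
        Grow each tree on a bootstrap resample of the training set (standard
        bagging); out-of-bag indices are retained per tree.  Off by default:
        tree diversity comes from the node-level sample/feature randomness,
        which keeps individual trees strong (the accurate-but-low-diversity
        regime the kappa-error diagnostics show).
    bootstrap_candidates : bool
        Fit each candidate node model on a bootstrap resample of its node's
        samples (gain is always judged on the full node).  Off by default:
        at the few-dozen-sample nodes this model targets, resampling
        degrades the candidates more than the full-node gain evaluation
        compensates; feature subsets, random model selection and random
        initializations provide the within-tree randomness.
    use_neural : bool
        Offer the neural splitter at nodes with more than 32 samples.
    """

    def __init__(
        self,
        n_estimators: int = 64,
        use_oracle: bool = True,
        oracle_mode: str = "candidate",
        max_features_fraction: float | str = 0.4,
        bootstrap: bool = False,
        bootstrap_candidates: bool = False,
        use_neural: bool = True,
        min_samples_split: int = 2,
        max_depth: int | None = None,
        oracle_probability: float = 0.0,
        gain_epsilon: float = 1e-9,
        impurity: str = "entropy",
        random_state: int | None = None,
    ):
        if n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        self.n_estimators = n_estimators
        self.use_oracle = use_oracle
        self.oracle_mode = oracle_mode
        self.max_features_fraction = max_features_fraction
        self.bootstrap = bootstrap
        self.bootstrap_candidates = bootstrap_candidates
        self.use_neural = use_neural
        self.min_samples_split = min_samples_split
        self.max_depth = max_depth
        self.oracle_probability = oracle_probability
        self.gain_epsilon = gain_epsilon
        self.impurity = impurity
        self.random_state = random_state

    def _tree_params(self) -> TreeParams:
        return TreeParams(
            use_oracle=self.use_oracle,
            oracle_mode=self.oracle_mode,
            oracle_probability=self.oracle_probability,
            max_features_fraction=self.max_features_fraction,
            min_samples_split=self.min_samples_split,
            max_depth=self.max_depth,
            gain_epsilon=self.gain_epsilon,
            impurity=self.impurity,
            use_neural=self.use_neural,
            bootstrap_candidates=self.bootstrap_candidates,
        )

    # ------------------------------------------------------------------
    def fit(self, X, y) -> "LANDMarkClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray([str(v) for v in np.asarray(y).ravel()])
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on sample count")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.n_features_in_ = X.shape[1]
        root_ss = np.random.SeedSequence(self.random_state)
        child_seeds = root_ss.spawn(self.n_estimators)
        params = self._tree_params()
        n = X.shape[0]
        self.trees_: list[LANDMarkTree] = []
        self.oob_indices_: list[np.ndarray] = []
        for ss in child_seeds:
            rng = np.random.default_rng(ss)
            for _attempt in range(2):
                idx = rng.integers(0, n, size=n) if self.bootstrap else np.arange(n)
                if len(np.unique(y[idx])) >= 2:
                    break
            # after a failed redraw the (possibly single-class) resample is
            # kept; build_tree degrades it to a single-leaf tree
            tree = build_tree(X[idx], y[idx], params, rng, classes=self.classes_)
            self.trees_.append(tree)
            self.oob_indices_.append(np.setdiff1d(np.arange(n), idx))
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "trees_"):
            raise RuntimeError("classifier is not fitted")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        return np.mean([t.predict_proba(X) for t in self.trees_], axis=0)

    def predict(self, X) -> np.ndarray:
        # argmax takes the first class on ties, matching the declared order
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def apply(self, X) -> np.ndarray:
        """(n_samples, n_trees) terminal leaf ids."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        return np.column_stack([t.apply(X) for t in self.trees_])

    def proximity(self, X, sample_ids=None) -> ProximityMatrix:
        """Fraction of trees in which each sample pair shares a terminal leaf."""
        leaves = self.apply(X)
        same = (leaves[:, None, :] == leaves[None, :, :]).mean(axis=2)
        np.fill_diagonal(same, 1.0)
        return ProximityMatrix(values=same, sample_ids=sample_ids)

    # ------------------------------------------------------------------
    @property
    def feature_importances_(self) -> np.ndarray:
        """Gain attribution: each internal node's achieved information gain,
        weighted by its sample share, distributed over the node's feature
        subset proportionally to absolute splitter coefficients (uniformly
        for oracle/neural nodes), summed over trees and normalized."""
        self._check_fitted()
        imp = np.zeros(self.n_features_in_)
        for tree in self.trees_:
            n_root = tree.root.n_samples
            for node in tree.iter_nodes():
                sp = node.splitter
                if sp is None or sp.gain <= 0:
                    continue
                weight = sp.gain * node.n_samples / n_root
                subset = (
                    np.arange(self.n_features_in_)
                    if sp.feature_subset is None
                    else sp.feature_subset
                )
                coef = getattr(sp.model, "coef_", None)
                if sp.family in ("oracle", "neural_net") or coef is None:
                    share = np.full(len(subset), 1.0 / len(subset))
                else:
                    mag = np.abs(np.atleast_2d(coef)).sum(axis=0)
                    share = mag / mag.sum() if mag.sum() > 0 else np.full(len(subset), 1.0 / len(subset))
                imp[subset] += weight * share
        total = imp.sum()
        return imp / total if total > 0 else imp

    # -- persistence ---------------------------------------------------
    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "format": "landmark-ensemble/1",
            "classes": [str(c) for c in self.classes_],
            "n_features": int(self.n_features_in_),
            "params": {
                "n_estimators": self.n_estimators,
                "use_oracle": self.use_oracle,
                "max_features_fraction": self.max_features_fraction,
                "random_state": self.random_state,
            },
            "trees": [t.to_dict() for t in self.trees_],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LANDMarkClassifier":
        if d.get("format") != "landmark-ensemble/1":
            raise ValueError("unrecognized ensemble document format")
        p = d["params"]
        obj = cls(
            n_estimators=p["n_estimators"],
            use_oracle=p["use_oracle"],
            max_features_fraction=p["max_features_fraction"],
            random_state=p["random_state"],
        )
        obj.classes_ = np.asarray(d["classes"])
        obj.n_features_in_ = int(d["n_features"])
        obj.trees_ = [LANDMarkTree.from_dict(t) for t in d["trees"]]
        obj.oob_indices_ = []
        return obj

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path: str) -> "LANDMarkClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
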