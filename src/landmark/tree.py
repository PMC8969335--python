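"""A single decision tree with learned oblique / non-linear node splits.

Construction: optionally pre-partition the root with a random linear oracle
(a hyperplane through the midpoint of two randomly chosen training samples,
each branch then modelled independently), then at every node fit the pool of
candidate models (see :mod:`landmark.splitters`), judge each fitted model's
partition by information gain on the node's labels, and pick uniformly at
random among the candidates whose gain ties the maximum (within
``gain_epsilon``).  A node becomes a leaf when it is pure, too small, at the
depth cap, or when no candidate achieves positive gain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .splitters import (
    DEFAULT_SPECS,
    FittedSplitter,
    SplitterSpec,
    fit_linear_splitter,
    select_hyperparameters,
)

__all__ = [
    "OracleUnavailable",
    "OracleHyperplane",
    "entropy",
    "gini_impurity",
    "information_gain",
    "choose_split",
    "draw_oracle",
    "TreeParams",
    "TreeNode",
    "LANDMarkTree",
    "build_tree",
]


class OracleUnavailable(RuntimeError):
    """Raised when no pair of distinct sample vectors exists for an oracle."""


@dataclass
class OracleHyperplane:
    """Random hyperplane through the midpoint of two training samples.

    ``side(x) = sign((b - a) · (x - (a + b)/2))``; points exactly on the
    hyperplane go to the positive ("right") side.
    """

    anchor_a: np.ndarray
    anchor_b: np.ndarray

    def __post_init__(self) -> None:
        self.anchor_a = np.asarray(self.anchor_a, dtype=float)
        self.anchor_b = np.asarray(self.anchor_b, dtype=float)
        if np.array_equal(self.anchor_a, self.anchor_b):
            raise ValueError("oracle anchors must be distinct vectors")
        self.midpoint = (self.anchor_a + self.anchor_b) / 2.0
        self.normal = self.anchor_b - self.anchor_a

    def predict(self, X: np.ndarray) -> np.ndarray:
        proj = (np.asarray(X, dtype=float) - self.midpoint) @ self.normal
        return np.where(proj >= 0.0, "right", "left")

    def to_dict(self) -> dict:
        return {
            "kind": "oracle",
            "anchor_a": self.anchor_a.tolist(),
            "anchor_b": self.anchor_b.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OracleHyperplane":
        return cls(anchor_a=np.asarray(d["anchor_a"]), anchor_b=np.asarray(d["anchor_b"]))


def draw_oracle(X: np.ndarray, rng: np.random.Generator, max_attempts: int = 10) -> OracleHyperplane:
    """Pick two distinct rows uniformly without replacement; redraw on
    identical vectors, failing over after ``max_attempts``."""
    n = X.shape[0]
    if n < 2:
        raise OracleUnavailable("need at least two samples")
    for _ in range(max_attempts):
        i, j = rng.choice(n, size=2, replace=False)
        if not np.array_equal(X[i], X[j]):
            return OracleHyperplane(anchor_a=X[i], anchor_b=X[j])
    raise OracleUnavailable("all sampled row pairs were identical vectors")


# ----------------------------------------------------------------------
def entropy(labels) -> float:
    """Shannon entropy of a label multiset, in bits."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty label set is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def gini_impurity(labels) -> float:
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("impurity of an empty label set is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(1.0 - np.sum(p * p))


_IMPURITY = {"entropy": entropy, "gini": gini_impurity}


def information_gain(parent_labels, branch_labels: Sequence, impurity: str = "entropy") -> float:
    """Impurity of the parent minus the size-weighted impurity of branches."""
    parent_labels = np.asarray(parent_labels)
    n = parent_labels.size
    total = sum(len(b) for b in branch_labels)
    if total != n:
        raise ValueError("branches must partition the parent exactly")
    h = _IMPURITY[impurity]
    child = sum(len(b) / n * h(b) for b in branch_labels if len(b) > 0)
    return float(h(parent_labels) - child)


def choose_split(
    candidates: list[FittedSplitter],
    rng: np.random.Generator,
    gain_epsilon: float = 1e-9,
) -> FittedSplitter | None:
    """Uniform random choice among candidates within ``gain_epsilon`` of the
    best gain; None when no candidate exceeds ``gain_epsilon``."""
    if not candidates:
        return None
    gains = np.array([c.gain for c in candidates])
    best = gains.max()
    if best <= gain_epsilon:
        return None
    tied = np.flatnonzero(gains >= best - gain_epsilon)
    return candidates[int(rng.choice(tied))]


# ----------------------------------------------------------------------
@dataclass
class TreeParams:
    """Knobs shared by tree and ensemble construction."""

    use_oracle: bool = True
    # "candidate": the oracle competes on information gain in every node's
    # pool; "root": Kuncheva-style mandatory root pre-partition
    oracle_mode: str = "candidate"
    oracle_probability: float = 0.0  # extra per-node mandatory-oracle chance
    max_features_fraction: float | str = 0.4  # fraction of features per node, or "sqrt"
    min_samples_split: int = 2
    max_depth: int | None = None
    gain_epsilon: float = 1e-9
    impurity: str = "entropy"
    use_neural: bool = True
    bootstrap_candidates: bool = False
    specs: list[SplitterSpec] = field(default_factory=lambda: list(DEFAULT_SPECS))


@dataclass
class TreeNode:
    node_id: int
    depth: int
    n_samples: int
    class_distribution: np.ndarray
    splitter: FittedSplitter | None = None
    children: dict = field(default_factory=dict)
    child_sizes: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.splitter is None


class LANDMarkTree:
    """One fitted tree; built via :func:`build_tree`."""

    def __init__(self, root: TreeNode, classes: np.ndarray, params: TreeParams, seed):
        self.root = root
        self.classes_ = np.asarray(classes)
        self.params = params
        self.seed = seed

    # -- routing -------------------------------------------------------
    def _route(self, node: TreeNode, X: np.ndarray, idx: np.ndarray, out_leaf, out_dist):
        if node.is_leaf or len(idx) == 0:
            out_leaf[idx] = node.node_id
            out_dist[idx] = node.class_distribution
            return
        labels = node.splitter.partition(X[idx])
        routed = np.zeros(len(idx), dtype=bool)
        for branch, child in node.children.items():
            mask = labels == branch
            routed |= mask
            self._route(child, X, idx[mask], out_leaf, out_dist)
        if not routed.all():
            # branch label unseen in training: follow the largest child
            fallback = max(node.children, key=lambda b: node.child_sizes.get(b, 0))
            self._route(node.children[fallback], X, idx[~routed], out_leaf, out_dist)

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_:
            raise ValueError(
                f"expected {self.n_features_} features, got shape {X.shape}"
            )
        return X

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._check_X(X)
        leaf = np.empty(X.shape[0], dtype=int)
        dist = np.empty((X.shape[0], len(self.classes_)))
        self._route(self.root, X, np.arange(X.shape[0]), leaf, dist)
        return dist

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Terminal leaf id for every sample."""
        X = self._check_X(X)
        leaf = np.empty(X.shape[0], dtype=int)
        dist = np.empty((X.shape[0], len(self.classes_)))
        self._route(self.root, X, np.arange(X.shape[0]), leaf, dist)
        return leaf

    def leaf_ids(self) -> list[int]:
        out: list[int] = []

        def walk(node: TreeNode):
            if node.is_leaf:
                out.append(node.node_id)
            for child in node.children.values():
                walk(child)

        walk(self.root)
        return out

    def iter_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children.values())

    # -- persistence ---------------------------------------------------
    def to_dict(self) -> dict:
        def node_dict(node: TreeNode) -> dict:
            return {
                "node_id": node.node_id,
                "depth": node.depth,
                "n_samples": node.n_samples,
                "class_distribution": node.class_distribution.tolist(),
                "splitter": None if node.splitter is None else node.splitter.to_dict(),
                "child_sizes": {str(k): int(v) for k, v in node.child_sizes.items()},
                "children": {str(k): node_dict(v) for k, v in node.children.items()},
            }

        return {
            "format": "landmark-tree/1",
            "classes": [str(c) for c in self.classes_],
            "n_features": int(self.n_features_),
            "seed": self.seed,
            "root": node_dict(self.root),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LANDMarkTree":
        if d.get("format") != "landmark-tree/1":
            raise ValueError("unrecognized tree document format")

        def build(nd: dict) -> TreeNode:
            node = TreeNode(
                node_id=int(nd["node_id"]),
                depth=int(nd["depth"]),
                n_samples=int(nd["n_samples"]),
                class_distribution=np.asarray(nd["class_distribution"], dtype=float),
                splitter=None
                if nd["splitter"] is None
                else FittedSplitter.from_dict(nd["splitter"]),
                child_sizes={k: int(v) for k, v in nd["child_sizes"].items()},
            )
            node.children = {k: build(v) for k, v in nd["children"].items()}
            return node

        tree = cls(
            root=build(d["root"]),
            classes=np.asarray(d["classes"]),
            params=TreeParams(),
            seed=d.get("seed"),
        )
        tree.n_features_ = int(d["n_features"])
        return tree

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path: str) -> "LANDMarkTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ----------------------------------------------------------------------
def _class_distribution(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    dist = np.array([np.sum(y == c) for c in classes], dtype=float)
    return dist / dist.sum()


def _fit_candidates(
    X: np.ndarray,
    y: np.ndarray,
    params: TreeParams,
    rng: np.random.Generator,
) -> list[FittedSplitter]:
    n, d = X.shape
    if params.max_features_fraction == "sqrt":
        subset_size = max(1, int(np.ceil(np.sqrt(d))))
    else:
        subset_size = max(1, int(np.ceil(float(params.max_features_fraction) * d)))

    def draw_subset():
        # each subset-using candidate draws its own random feature subset
        if d < 4:
            return None
        return np.sort(rng.choice(d, size=subset_size, replace=False))

    candidates: list[FittedSplitter] = []
    for spec in params.specs:
        if spec.family == "neural_net":
            if not params.use_neural or n < spec.min_samples_to_fit:
                continue
            fs = draw_subset()
            Xs = X if fs is None else X[:, fs]
            Xfit, yfit = Xs, y
            if params.bootstrap_candidates:
                idx = rng.integers(0, n, size=n)
                if len(np.unique(y[idx])) >= 2:
                    Xfit, yfit = Xs[idx], y[idx]
            from .neural import NeuralSplitter

            net = NeuralSplitter(random_state=int(rng.integers(2**31 - 1)))
            net.fit(Xfit, yfit)
            fitted = FittedSplitter(family="neural_net", model=net, feature_subset=fs)
        else:
            if n < spec.min_samples_to_fit:
                continue
            fs = draw_subset() if spec.uses_random_feature_subset else None
            Xsel = X if fs is None else X[:, fs]
            hp = select_hyperparameters(spec, Xsel, y, rng)
            fitted = fit_linear_splitter(
                spec, X, y, fs, hp, rng, bootstrap=params.bootstrap_candidates
            )
        part = fitted.partition(X)
        branches = [y[part == b] for b in np.unique(part)]
        fitted.gain = information_gain(y, branches, impurity=params.impurity)
        candidates.append(fitted)
    if params.use_oracle and params.oracle_mode == "candidate":
        try:
            oracle = draw_oracle(X, rng)
        except OracleUnavailable:
            oracle = None
        if oracle is not None:
            fitted = FittedSplitter(family="oracle", model=oracle)
            part = fitted.partition(X)
            branches = [y[part == b] for b in np.unique(part)]
            fitted.gain = information_gain(y, branches, impurity=params.impurity)
            candidates.append(fitted)
    return candidates


def build_tree(
    X: np.ndarray,
    y,
    params: TreeParams | None = None,
    rng: np.random.Generator | int | None = None,
    classes=None,
) -> LANDMarkTree:
    """Grow one tree.  ``classes`` fixes the probability-column order (the
    ensemble passes its own); defaults to the sorted labels present."""
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(v) for v in np.asarray(y).ravel()])
    if params is None:
        params = TreeParams()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if classes is None:
        classes = np.unique(y)
    classes = np.asarray([str(c) for c in classes])
    if len(np.unique(y)) < 2:
        # degenerate input: a single leaf
        root = TreeNode(0, 0, len(y), _class_distribution(y, classes))
        tree = LANDMarkTree(root, classes, params, seed)
        tree.n_features_ = X.shape[1]
        return tree

    counter = iter(range(10**9))

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(
            node_id=next(counter),
            depth=depth,
            n_samples=len(idx),
            class_distribution=_class_distribution(y[idx], classes),
        )
        ys = y[idx]
        pure = len(np.unique(ys)) < 2
        at_depth_cap = params.max_depth is not None and depth >= params.max_depth
        if pure or len(idx) < params.min_samples_split or at_depth_cap:
            return node

        use_oracle_here = params.use_oracle and (
            (params.oracle_mode == "root" and depth == 0)
            or (params.oracle_probability > 0 and rng.random() < params.oracle_probability)
        )
        if use_oracle_here:
            try:
                oracle = draw_oracle(X[idx], rng)
            except OracleUnavailable:
                oracle = None
            if oracle is not None:
                part = oracle.predict(X[idx])
                sides = np.unique(part)
                if len(sides) == 2:
                    branches = [ys[part == s] for s in sides]
                    splitter = FittedSplitter(family="oracle", model=oracle)
                    splitter.gain = information_gain(ys, branches, impurity=params.impurity)
                    node.splitter = splitter
                    for s in sides:
                        child_idx = idx[part == s]
                        node.child_sizes[str(s)] = len(child_idx)
                        node.children[str(s)] = grow(child_idx, depth + 1)
                    return node
                # degenerate oracle partition: fall through to model splits

        candidates = _fit_candidates(X[idx], ys, params, rng)
        chosen = choose_split(candidates, rng, params.gain_epsilon)
        if chosen is None:
            return node
        part = chosen.partition(X[idx])
        node.splitter = chosen
        for b in np.unique(part):
            child_idx = idx[part == b]
            node.child_sizes[str(b)] = len(child_idx)
            node.children[str(b)] = grow(child_idx, depth + 1)
        return node

    root = grow(np.arange(X.shape[0]), 0)
    tree = LANDMarkTree(root, classes, params, seed)
    tree.n_features_ = X.shape[1]
    return tree
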