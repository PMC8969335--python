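import numpy as np
import pytest

import landmark as lm
from landmark.tree import (
    OracleUnavailable,
    TreeParams,
    choose_split,
    draw_oracle,
    gini_impurity,
)
from landmark.splitters import FittedSplitter


class TestEntropy:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            (list("aabb"), 1.0),
            (list("aaaa"), 0.0),
            (list("aaab"), -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))),
        ],
    )
    def test_values(self, labels, expected):
        assert lm.entropy(labels) == pytest.approx(expected, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lm.entropy([])

    def test_gini_bounds(self):
        assert gini_impurity(list("aabb")) == pytest.approx(0.5)
        assert gini_impurity(list("aaaa")) == 0.0


class TestInformationGain:
    def test_pure_two_way_split(self):
        assert lm.information_gain(list("aabb"), [list("aa"), list("bb")]) == pytest.approx(1.0)

    def test_trivial_partition_gains_nothing(self):
        assert lm.information_gain(list("aabb"), [list("aabb")]) == pytest.approx(0.0)

    def test_closed_form_uneven_split(self):
        got = lm.information_gain(list("aabb"), [list("aab"), list("b")])
        assert got == pytest.approx(1.0 - 0.75 * lm.entropy(list("aab")), abs=1e-4)
        assert got == pytest.approx(0.3113, abs=1e-4)

    def test_incomplete_partition_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            lm.information_gain(list("aabb"), [list("aa")])

    def test_bounded_by_parent_entropy(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            y = rng.choice(list("abc"), 30)
            cut = rng.integers(1, 29)
            g = lm.information_gain(y, [y[:cut], y[cut:]])
            assert -1e-12 <= g <= lm.entropy(y) + 1e-12


class TestOracle:
    def test_hand_computed_geometry(self):
        h = lm.OracleHyperplane(np.array([0.0, 0.0]), np.array([2.0, 0.0]))
        np.testing.assert_array_equal(h.midpoint, [1.0, 0.0])
        np.testing.assert_array_equal(h.normal, [2.0, 0.0])
        assert h.predict(np.array([[3.0, 0.0]]))[0] == "right"
        assert h.predict(np.array([[-1.0, 0.0]]))[0] == "left"
        # anchors land on opposite sides
        sides = h.predict(np.array([[0.0, 0.0], [2.0, 0.0]]))
        assert set(sides) == {"left", "right"}

    def test_on_hyperplane_point_goes_positive(self):
        h = lm.OracleHyperplane(np.array([0.0, 0.0]), np.array([2.0, 0.0]))
        assert h.predict(np.array([[1.0, 5.0]]))[0] == "right"

    def test_identical_anchors_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            lm.OracleHyperplane(np.ones(3), np.ones(3))

    def test_draw_from_duplicated_rows_unavailable(self):
        X = np.ones((6, 4))
        with pytest.raises(OracleUnavailable):
            draw_oracle(X, np.random.default_rng(0))

    def test_draw_produces_distinct_anchors(self):
        rng = np.random.default_rng(1)
        X = rng.random((10, 3))
        h = draw_oracle(X, rng)
        assert not np.array_equal(h.anchor_a, h.anchor_b)


class _ConstSplitter(FittedSplitter):
    """Candidate stub carrying a preset gain."""

    def __init__(self, gain):
        super().__init__(family="stub", model=None)
        self.gain = gain


class TestChooseSplit:
    def test_clear_winner_always_chosen(self):
        cands = [_ConstSplitter(0.8), _ConstSplitter(0.3)]
        for seed in range(20):
            assert choose_split(cands, np.random.default_rng(seed)) is cands[0]

    def test_ties_split_evenly(self):
        cands = [_ConstSplitter(0.8), _ConstSplitter(0.8)]
        rng = np.random.default_rng(0)
        wins = sum(choose_split(cands, rng) is cands[0] for _ in range(1000))
        # binomial(1000, .5): +-4 sigma of 500 is ~(437, 563)
        assert 437 <= wins <= 563

    def test_no_positive_gain_signals_leaf(self):
        assert choose_split([_ConstSplitter(0.0)], np.random.default_rng(0)) is None


class TestBuildTree:
    def test_separable_data_reaches_perfect_training_accuracy(self, blobs):
        X, y = blobs
        tree = lm.build_tree(X, y, TreeParams(use_oracle=False, use_neural=False), rng=0)
        assert (tree.predict(X) == y).mean() == 1.0
        # strong oblique learners separate blobs in a single split
        assert all(child.is_leaf for child in tree.root.children.values())

    def test_pure_labels_make_single_leaf(self):
        X = np.random.default_rng(0).random((6, 3))
        tree = lm.build_tree(X, ["a"] * 6, rng=0)
        assert tree.root.is_leaf

    def test_xor_defeats_linear_splitters(self, xor_points):
        # with only linear candidates and no oracle, the four XOR points
        # cannot be classified beyond the majority rate
        X, y = xor_points
        params = TreeParams(use_oracle=False, use_neural=False, bootstrap_candidates=False)
        tree = lm.build_tree(X, y, params, rng=0)
        acc = (tree.predict(X) == y).mean()
        assert acc <= 0.75
        for node in tree.iter_nodes():
            if node.splitter is not None:
                assert node.splitter.gain <= lm.entropy(y) - 0.5

    def test_depth_cap_respected(self, blobs):
        X, y = blobs
        tree = lm.build_tree(
            X, y, TreeParams(use_oracle=False, use_neural=False, max_depth=0), rng=0
        )
        assert tree.root.is_leaf

    def test_probability_rows_sum_to_one(self, blobs):
        X, y = blobs
        tree = lm.build_tree(X, y, TreeParams(use_neural=False), rng=3)
        rng = np.random.default_rng(0)
        proba = tree.predict_proba(rng.normal(1.5, 2.0, (25, 5)))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)

    def test_seeded_build_is_reproducible(self, blobs):
        X, y = blobs
        params = TreeParams(use_neural=False)
        t1 = lm.build_tree(X, y, params, rng=7)
        t2 = lm.build_tree(X, y, params, rng=7)
        Xq = np.random.default_rng(1).normal(1.5, 2.0, (30, 5))
        np.testing.assert_array_equal(t1.predict_proba(Xq), t2.predict_proba(Xq))
        assert t1.to_dict() == t2.to_dict()


class TestApplyAndPredict:
    def test_training_samples_hit_pure_leaves(self, blobs):
        X, y = blobs
        tree = lm.build_tree(X, y, TreeParams(use_neural=False), rng=0)
        proba = tree.predict_proba(X)
        expected = (proba.argmax(axis=1) == (y == "B").astype(int)).all()
        assert expected
        np.testing.assert_allclose(proba.max(axis=1), 1.0)

    def test_identical_samples_share_a_leaf(self, blobs):
        X, y = blobs
        tree = lm.build_tree(X, y, TreeParams(use_neural=False), rng=0)
        two = np.vstack([X[0], X[0]])
        ids = tree.apply(two)
        assert ids[0] == ids[1]

    def test_leaf_ids_come_from_declared_leaves(self, blobs):
        X, y = blobs
        tree = lm.build_tree(X, y, TreeParams(use_neural=False), rng=2)
        declared = set(tree.leaf_ids())
        assert set(tree.apply(X).tolist()) <= declared

    def test_single_leaf_tree_returns_root_distribution(self):
        X = np.random.default_rng(0).random((8, 2))
        tree = lm.build_tree(X, ["a"] * 8, rng=0, classes=["a", "b"])
        proba = tree.predict_proba(X)
        np.testing.assert_array_equal(proba, np.tile([1.0, 0.0], (8, 1)))
        assert len(set(tree.apply(X).tolist())) == 1

    def test_dimension_mismatch_rejected(self, blobs):
        X, y = blobs
        tree = lm.build_tree(X, y, TreeParams(use_neural=False), rng=0)
        with pytest.raises(ValueError, match="features"):
            tree.predict(X[:, :3])


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path, blobs):
        X, y = blobs
        tree = lm.build_tree(X, y, TreeParams(use_neural=False), rng=5)
        path = str(tmp_path / "tree.json")
        tree.to_json(path)
        back = lm.LANDMarkTree.from_json(path)
        Xq = np.random.default_rng(2).normal(1.5, 2.0, (40, 5))
        np.testing.assert_allclose(tree.predict_proba(Xq), back.predict_proba(Xq))
        np.testing.assert_array_equal(tree.apply(Xq), back.apply(Xq))

    def test_root_oracle_tree_round_trip(self, blobs):
        # mandatory root pre-partition: the serialized document must carry
        # the hyperplane and reproduce its routing exactly
        X, y = blobs
        params = TreeParams(use_neural=False, oracle_mode="root")
        tree = lm.build_tree(X, y, params, rng=1)
        assert tree.root.splitter.family == "oracle"
        back = lm.LANDMarkTree.from_dict(tree.to_dict())
        Xq = np.random.default_rng(3).normal(1.5, 2.0, (30, 5))
        np.testing.assert_allclose(tree.predict_proba(Xq), back.predict_proba(Xq))


class TestSingleTreeNonLinearAdvantage:
    def test_single_tree_beats_axis_aligned_cart_on_circles(self):
        """A single tree with learned oblique/non-linear node splits
        generalizes better than a single axis-aligned CART tree on the
        concentric-circles geometry, where CART overfits the noise
        (mean over 8 seeds)."""
        from sklearn.tree import DecisionTreeClassifier

        ours, cart = [], []
        for seed in range(8):
            X, y = lm.make_concentric_rings(150, noise=0.1, rng=seed)
            Xt, yt = lm.make_concentric_rings(400, noise=0.1, rng=1000 + seed)
            tree = lm.build_tree(X, y, TreeParams(use_neural=True), rng=seed)
            ours.append((tree.predict(Xt) == yt).mean())
            dt = DecisionTreeClassifier(random_state=seed).fit(X, y)
            cart.append((dt.predict(Xt) == yt).mean())
        assert np.mean(ours) > np.mean(cart)
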