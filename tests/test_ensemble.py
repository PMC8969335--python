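import numpy as np
import pytest

import landmark as lm
from landmark.ensemble import ProximityMatrix


class _StubTree:
    def __init__(self, proba=None, leaves=None):
        self._proba = proba
        self._leaves = leaves

    def predict_proba(self, X):
        return np.tile(self._proba, (len(X), 1))

    def apply(self, X):
        return np.asarray(self._leaves)


def stub_ensemble(trees, classes=("a", "b")):
    clf = lm.LANDMarkClassifier(n_estimators=len(trees))
    clf.classes_ = np.asarray(classes)
    clf.n_features_in_ = 2
    clf.trees_ = trees
    clf.oob_indices_ = []
    return clf


class TestEnsemblePredictions:
    def test_single_tree_ensemble_equals_its_tree(self, blobs):
        X, y = blobs
        clf = lm.LANDMarkClassifier(
            n_estimators=1, use_neural=False, random_state=0
        ).fit(X, y)
        np.testing.assert_array_equal(
            clf.predict_proba(X), clf.trees_[0].predict_proba(X)
        )

    def test_separable_training_accuracy(self, fitted_small_ensemble):
        clf, X, y = fitted_small_ensemble
        assert lm.balanced_accuracy_from_labels(y, clf.predict(X)) == 1.0

    def test_rows_sum_to_one(self, fitted_small_ensemble):
        clf, X, _ = fitted_small_ensemble
        Xq = np.random.default_rng(0).normal(1.5, 2.0, (30, 5))
        np.testing.assert_allclose(clf.predict_proba(Xq).sum(axis=1), 1.0)

    def test_split_vote_breaks_to_first_class(self):
        clf = stub_ensemble(
            [_StubTree(proba=np.array([1.0, 0.0])), _StubTree(proba=np.array([0.0, 1.0]))]
        )
        X = np.zeros((3, 2))
        np.testing.assert_allclose(clf.predict_proba(X), 0.5)
        assert list(clf.predict(X)) == ["a", "a", "a"]

    def test_unanimous_vote(self):
        clf = stub_ensemble([_StubTree(proba=np.array([0.0, 1.0]))] * 3)
        np.testing.assert_allclose(clf.predict_proba(np.zeros((2, 2)))[:, 1], 1.0)

    def test_seeded_double_fit_is_identical(self, blobs):
        X, y = blobs
        kw = dict(n_estimators=3, use_neural=False, random_state=11)
        p1 = lm.LANDMarkClassifier(**kw).fit(X, y).predict_proba(X)
        p2 = lm.LANDMarkClassifier(**kw).fit(X, y).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_rejects_single_class(self):
        with pytest.raises(ValueError, match="two classes"):
            lm.LANDMarkClassifier(n_estimators=1).fit(np.ones((4, 2)), ["a"] * 4)

    def test_rejects_zero_estimators(self):
        with pytest.raises(ValueError):
            lm.LANDMarkClassifier(n_estimators=0)


class TestProximity:
    def test_same_leaf_single_tree(self):
        clf = stub_ensemble([_StubTree(leaves=[7, 7])])
        np.testing.assert_array_equal(
            clf.proximity(np.zeros((2, 2))).values, np.ones((2, 2))
        )

    def test_never_cooccurring_pair(self):
        clf = stub_ensemble([_StubTree(leaves=[1, 2]), _StubTree(leaves=[3, 4])])
        prox = clf.proximity(np.zeros((2, 2))).values
        assert prox[0, 1] == 0.0 and prox[0, 0] == 1.0

    def test_three_tree_hand_trace(self):
        # sample pair (0,1): together in trees 1 and 3 -> 2/3
        clf = stub_ensemble(
            [
                _StubTree(leaves=[5, 5, 6]),
                _StubTree(leaves=[1, 2, 2]),
                _StubTree(leaves=[9, 9, 9]),
            ]
        )
        prox = clf.proximity(np.zeros((3, 2))).values
        expected = np.array(
            [[3, 2, 1], [2, 3, 2], [1, 2, 3]], dtype=float
        ) / 3.0
        np.testing.assert_allclose(prox, expected)

    def test_fitted_model_proximity_contract(self, fitted_small_ensemble):
        clf, X, _ = fitted_small_ensemble
        p = clf.proximity(X).values
        np.testing.assert_allclose(np.diag(p), 1.0)
        np.testing.assert_allclose(p, p.T)
        assert p.min() >= 0.0 and p.max() <= 1.0


class TestDissimilarity:
    @pytest.mark.parametrize("p, d", [(1.0, 0.0), (0.0, 1.0), (0.75, 0.5)])
    def test_sqrt_one_minus_p(self, p, d):
        prox = ProximityMatrix(values=np.array([[1.0, p], [p, 1.0]]))
        got = lm.proximity_to_dissimilarity(prox)
        assert got[0, 1] == pytest.approx(d)
        assert got[0, 0] == 0.0


class TestPCoA:
    def test_equilateral_triangle_splits_variance_evenly(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = lm.pcoa(D)
        np.testing.assert_allclose(res.explained_variance_ratio, [0.5, 0.5], atol=1e-12)

    def test_collinear_points_load_on_first_axis(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        D = np.abs(x[:, None] - x[None, :])
        res = lm.pcoa(D)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(0)
        pts = rng.random((12, 4))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = lm.pcoa(D)
        C = res.coordinates
        D2 = np.linalg.norm(C[:, None] - C[None, :], axis=-1)
        np.testing.assert_allclose(D2, D, atol=1e-8)

    def test_ratios_are_sorted_and_normalized(self, fitted_small_ensemble):
        clf, X, _ = fitted_small_ensemble
        D = lm.proximity_to_dissimilarity(clf.proximity(X))
        res = lm.pcoa(D)
        r = res.explained_variance_ratio
        assert np.all(np.diff(r) <= 1e-12)
        assert r.sum() <= 1.0 + 1e-9

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        pts = rng.random((10, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ours = lm.pcoa(D)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D))
        k = 3
        np.testing.assert_allclose(
            ours.explained_variance_ratio[:k],
            theirs.proportion_explained.values[:k],
            atol=1e-8,
        )
        for axis in range(k):
            a = ours.coordinates[:, axis]
            b = theirs.samples.values[:, axis]
            assert abs(np.corrcoef(a, b)[0, 1]) == pytest.approx(1.0, abs=1e-6)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            lm.pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_degenerate_dissimilarity_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            lm.pcoa(np.zeros((3, 3)))


class TestSupervisedSeparation:
    def test_first_axis_separates_classes_on_accurate_model(self, blobs):
        X, y = blobs
        clf = lm.LANDMarkClassifier(n_estimators=8, use_neural=False, random_state=1).fit(X, y)
        assert lm.balanced_accuracy_from_labels(y, clf.predict(X)) > 0.9
        D = lm.proximity_to_dissimilarity(clf.proximity(X))
        res = lm.pcoa(D)
        c0 = res.coordinates[np.asarray(y) == "A", 0].mean()
        c1 = res.coordinates[np.asarray(y) == "B", 0].mean()
        spread = res.coordinates[:, 0].std()
        assert abs(c0 - c1) > spread


class TestEnsembleSerialization:
    def test_json_round_trip_preserves_predictions(self, tmp_path, fitted_small_ensemble):
        clf, X, _ = fitted_small_ensemble
        path = str(tmp_path / "model.json")
        clf.to_json(path)
        back = lm.LANDMarkClassifier.from_json(path)
        np.testing.assert_allclose(back.predict_proba(X), clf.predict_proba(X))
        np.testing.assert_array_equal(back.apply(X), clf.apply(X))


class TestFeatureImportances:
    def test_importances_normalized_and_nonnegative(self, fitted_small_ensemble):
        clf, _, _ = fitted_small_ensemble
        imp = clf.feature_importances_
        assert imp.shape == (5,)
        assert np.all(imp >= 0)
        assert imp.sum() == pytest.approx(1.0)
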