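import numpy as np
import pytest

import landmark as lm
from landmark.splitters import (
    DEFAULT_SPECS,
    SGD_LOSSES,
    FittedSplitter,
    LinearDecision,
    fit_linear_splitter,
    select_hyperparameters,
)
from landmark.tree import TreeParams, _fit_candidates


def spec_for(family):
    return next(s for s in DEFAULT_SPECS if s.family == family)


@pytest.fixture(scope="module")
def separable_node():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 0.4, (50, 6)), rng.normal(3, 0.4, (50, 6))])
    y = np.array(["A"] * 50 + ["B"] * 50)
    return X, y


class TestCandidatePoolComposition:
    def test_full_feature_families_never_subset(self):
        for family in ("logistic_l1", "sgd_elasticnet"):
            assert not spec_for(family).uses_random_feature_subset

    def test_neural_threshold_is_33_samples(self):
        assert spec_for("neural_net").min_samples_to_fit == 33

    def test_small_node_pool_excludes_ridge_and_neural(self, separable_node):
        X, y = separable_node
        idx = np.r_[0:3, 50:53]  # 6-sample node
        cands = _fit_candidates(
            X[idx], y[idx], TreeParams(use_neural=True), np.random.default_rng(0)
        )
        families = [c.family for c in cands]
        assert "ridge" not in families and "neural_net" not in families
        assert sorted(f for f in families if f != "oracle") == sorted(
            ["logistic_l2", "logistic_l1", "linear_svc", "sgd_l2", "sgd_elasticnet"]
        )

    def test_medium_node_pool_has_six_linear_families_plus_oracle(self, separable_node):
        X, y = separable_node
        idx = np.r_[0:10, 50:60]  # 20 samples: ridge in, neural out
        cands = _fit_candidates(
            X[idx], y[idx], TreeParams(use_neural=True), np.random.default_rng(0)
        )
        families = sorted(c.family for c in cands)
        assert families == sorted(
            ["logistic_l2", "logistic_l1", "linear_svc", "sgd_l2",
             "sgd_elasticnet", "ridge", "oracle"]
        )

    def test_oracle_candidate_respects_policy(self, separable_node):
        X, y = separable_node
        idx = np.r_[0:10, 50:60]
        cands = _fit_candidates(
            X[idx], y[idx], TreeParams(use_oracle=False), np.random.default_rng(0)
        )
        assert "oracle" not in [c.family for c in cands]

    def test_large_node_pool_includes_neural(self, separable_node):
        X, y = separable_node
        cands = _fit_candidates(
            X, y, TreeParams(use_neural=True), np.random.default_rng(0)
        )
        assert "neural_net" in [c.family for c in cands]


class TestHyperparameterSelection:
    def test_tiny_node_skips_grid_search(self):
        X = np.random.default_rng(0).random((6, 3))
        y = np.array(list("aaabbb"))
        params = select_hyperparameters(
            spec_for("logistic_l2"), X, y, np.random.default_rng(0)
        )
        assert params.C == 1.0

    def test_tiny_sgd_node_gets_random_loss(self):
        X = np.random.default_rng(0).random((5, 3))
        y = np.array(list("aabbb"))
        seen = set()
        for seed in range(30):
            p = select_hyperparameters(
                spec_for("sgd_l2"), X, y, np.random.default_rng(seed)
            )
            assert p.alpha == 1.0
            seen.add(p.loss)
        assert seen == set(SGD_LOSSES)

    def test_separable_node_returns_first_grid_value(self, separable_node):
        # every C separates perfectly, so the tie resolves to the first
        # logarithmically spaced value
        X, y = separable_node
        p = select_hyperparameters(
            spec_for("logistic_l2"), X, y, np.random.default_rng(0)
        )
        assert p.C == pytest.approx(1e-4)

    def test_fold_count_shrinks_with_smallest_class(self):
        # 8v3: only 3 stratified folds are possible; search still runs
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 1, (8, 4)), rng.normal(4, 1, (3, 4))])
        y = np.array(["a"] * 8 + ["b"] * 3)
        p = select_hyperparameters(spec_for("linear_svc"), X, y, np.random.default_rng(0))
        assert p.C in [0.001, 0.01, 0.1, 1.0, 10.0, 100.0]


class TestFitLinearSplitter:
    @pytest.mark.parametrize(
        "family", ["logistic_l2", "logistic_l1", "linear_svc", "sgd_l2", "sgd_elasticnet", "ridge"]
    )
    def test_separable_partition_recovers_labels(self, separable_node, family):
        X, y = separable_node
        spec = spec_for(family)
        params = select_hyperparameters(spec, X, y, np.random.default_rng(0))
        fitted = fit_linear_splitter(
            spec, X, y, None, params, np.random.default_rng(0), bootstrap=False
        )
        np.testing.assert_array_equal(fitted.partition(X), y)

    def test_single_class_node_rejected(self):
        from landmark.splitters import RegularizationParams

        X = np.random.default_rng(0).random((5, 2))
        with pytest.raises(ValueError, match="single-class"):
            fit_linear_splitter(
                spec_for("logistic_l2"), X, np.array(["a"] * 5), None,
                RegularizationParams(C=1.0), np.random.default_rng(0),
            )

    def test_ridge_refused_at_tiny_nodes(self):
        from landmark.splitters import RegularizationParams

        X = np.random.default_rng(0).random((6, 2))
        y = np.array(list("aaabbb"))
        with pytest.raises(ValueError, match="ridge"):
            fit_linear_splitter(
                spec_for("ridge"), X, y, None, RegularizationParams(), np.random.default_rng(0)
            )

    def test_subset_restriction_is_respected(self, separable_node):
        from landmark.splitters import RegularizationParams

        X, y = separable_node
        subset = np.array([0, 2])
        fitted = fit_linear_splitter(
            spec_for("logistic_l2"), X, y, subset,
            RegularizationParams(C=1.0), np.random.default_rng(0), bootstrap=False,
        )
        assert fitted.model.coef_.shape[1] == 2
        # permuting unused columns cannot change the partition
        Xp = X.copy()
        Xp[:, 1] = np.random.default_rng(1).permutation(Xp[:, 1])
        np.testing.assert_array_equal(fitted.partition(X), fitted.partition(Xp))

    def test_full_feature_family_sees_everything(self, separable_node):
        X, y = separable_node
        cands = _fit_candidates(
            X, y, TreeParams(use_neural=False), np.random.default_rng(0)
        )
        by_family = {c.family: c for c in cands}
        assert by_family["logistic_l1"].feature_subset is None
        assert by_family["logistic_l2"].feature_subset is not None

    def test_bounded_gain_at_skewed_nodes(self):
        # a 95%-majority node cannot yield gain above its own entropy
        rng = np.random.default_rng(5)
        X = rng.random((40, 6))
        y = np.array(["a"] * 38 + ["b"] * 2)
        cands = _fit_candidates(X, y, TreeParams(use_neural=False), rng)
        cap = lm.entropy(y) + 1e-9
        assert all(c.gain <= cap for c in cands)

    def test_seeded_refit_is_identical(self, separable_node):
        X, y = separable_node
        a = _fit_candidates(X, y, TreeParams(use_neural=False), np.random.default_rng(42))
        b = _fit_candidates(X, y, TreeParams(use_neural=False), np.random.default_rng(42))
        for ca, cb in zip(a, b):
            assert ca.family == cb.family
            assert ca.gain == cb.gain
            np.testing.assert_array_equal(ca.partition(X), cb.partition(X))


class TestSplitterSerialization:
    def test_linear_round_trip(self, separable_node):
        from landmark.splitters import RegularizationParams

        X, y = separable_node
        fitted = fit_linear_splitter(
            spec_for("linear_svc"), X, y, None,
            RegularizationParams(C=1.0), np.random.default_rng(0), bootstrap=False,
        )
        back = FittedSplitter.from_dict(fitted.to_dict())
        assert isinstance(back.model, LinearDecision)
        np.testing.assert_array_equal(back.partition(X), fitted.partition(X))
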