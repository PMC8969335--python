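import numpy as np
import pytest

import landmark as lm


@pytest.fixture(scope="session")
def blobs():
    """Two well-separated Gaussian clusters — linearly separable."""
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0.0, 0.5, (20, 5)), rng.normal(3.0, 0.5, (20, 5))])
    y = np.array(["A"] * 20 + ["B"] * 20)
    return X, y


@pytest.fixture(scope="session")
def xor_points():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
    y = np.array(["A", "A", "B", "B"])
    return X, y


@pytest.fixture(scope="session")
def synthetic_small():
    """One seeded synthetic presence-absence dataset (48 x 150, 25 planted)."""
    rng = np.random.default_rng(42)
    baseline = lm.generate_baseline(150, rng=rng)
    return lm.generate_dataset(
        baseline, lm.PerturbationSpec(n_perturbed=25), rng=rng
    )


@pytest.fixture(scope="session")
def fitted_small_ensemble(blobs):
    """A 5-tree ensemble on separable blobs (no neural splitter for speed)."""
    X, y = blobs
    clf = lm.LANDMarkClassifier(
        n_estimators=5, use_neural=False, random_state=0
    ).fit(X, y)
    return clf, X, y
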