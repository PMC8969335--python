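"""Synthetic presence-absence datasets with planted perturbed features.

The generator emulates a two-condition ASV occurrence experiment: every
feature has a baseline occurrence probability ``p_O``; in the treatment
group a chosen subset of features has its presence *odds* multiplied by a
likelihood factor ``p_N`` drawn from {0.1, 0.125, 0.25, 0.5, 2, 4, 8, 10},
i.e. ``log(q / (1 - q)) = log(p_O / (1 - p_O)) + log(p_N)``.  After the two
blocks are drawn, 5% of features (chosen at random) have their entries
shuffled across all samples, injecting label-independent noise.  Each
dataset holds 48 samples, 24 controls and 24 treatments, and records the
mask of truly perturbed features for feature-recovery scoring.

Baselines can be estimated from a real presence-absence table or drawn from
a Beta sparsity profile (a self-contained stand-in emulating the occupancy
spectrum of amplicon tables).

2-D toy generators (two spirals, concentric rings) for probing non-linear
decision boundaries also live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist
from sklearn.datasets import make_circles

from .table import FeatureTable, LabelVector

__all__ = [
    "DEFAULT_LIKELIHOODS",
    "PerturbationSpec",
    "SyntheticDataset",
    "estimate_baseline_probs",
    "perturb_probability",
    "generate_baseline",
    "generate_dataset",
    "make_two_spirals",
    "make_concentric_rings",
]

DEFAULT_LIKELIHOODS = (0.1, 0.125, 0.25, 0.5, 2.0, 4.0, 8.0, 10.0)


@dataclass
class PerturbationSpec:
    """Design of one synthetic scenario."""

    n_perturbed: int = 50
    likelihood_choices: tuple = DEFAULT_LIKELIHOODS
    shuffle_fraction: float = 0.05
    n_control: int = 24
    n_treatment: int = 24
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.likelihood_choices):
            raise ValueError("likelihood choices must be positive")
        if not 0.0 <= self.shuffle_fraction <= 1.0:
            raise ValueError("shuffle_fraction must be in [0, 1]")


@dataclass
class SyntheticDataset:
    table: FeatureTable
    labels: LabelVector
    truth_mask: np.ndarray  # bool, per feature
    applied_likelihoods: np.ndarray  # p_N per feature; NaN when unperturbed
    shuffled_features: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    spec: PerturbationSpec | None = None

    @property
    def truth_features(self) -> list[str]:
        return [f for f, m in zip(self.table.feature_ids, self.truth_mask) if m]


def estimate_baseline_probs(table: FeatureTable) -> np.ndarray:
    """Per-feature occurrence frequency, clipped to [1/(2n), 1 - 1/(2n)] so
    the log-odds in the perturbation model stay finite."""
    if not table.is_binary:
        raise ValueError("baseline probabilities need a presence-absence table")
    n = table.n_samples
    freq = table.values.mean(axis=0)
    eps = 1.0 / (2.0 * n)
    return np.clip(freq, eps, 1.0 - eps)


def perturb_probability(p_o, p_n):
    """Closed-form solution of the odds perturbation:
    q = p_O * p_N / (1 - p_O + p_O * p_N)."""
    p_o = np.asarray(p_o, dtype=float)
    p_n = np.asarray(p_n, dtype=float)
    if np.any(p_o <= 0) or np.any(p_o >= 1):
        raise ValueError("p_O must lie strictly inside (0, 1)")
    if np.any(p_n <= 0):
        raise ValueError("p_N must be positive")
    q = (p_o * p_n) / (1.0 - p_o + p_o * p_n)
    return float(q) if q.ndim == 0 else q


def generate_baseline(
    n_features: int,
    sparsity_profile: tuple[float, float] = (0.6, 3.4),
    min_occupancy: float = 2.0 / 24.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw per-feature baseline probabilities from a Beta occupancy profile.

    The default Beta(0.6, 3.4) is skewed sparse (many rare features, few
    ubiquitous ones), truncated below at ``min_occupancy``: a baseline
    estimated from a prevalence-filtered table (features kept only when seen
    in >= 2 of 24 samples) cannot contain occurrence probabilities far below
    2/24.  The truncated default has mean occupancy ~0.22.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    a, b = sparsity_profile
    lo_cdf = float(beta_dist.cdf(min_occupancy, a, b))
    u = rng.random(n_features)
    p = beta_dist.ppf(lo_cdf + u * (1.0 - lo_cdf), a, b)
    return np.clip(p, min_occupancy, 1.0 - 1.0 / 96.0)


def generate_dataset(
    baseline_probs: np.ndarray,
    spec: PerturbationSpec | None = None,
    rng: np.random.Generator | int | None = None,
    control_rows: np.ndarray | None = None,
    independent_treatment: bool = False,
) -> SyntheticDataset:
    """Draw one synthetic presence-absence dataset.

    The control block is feature-wise Bernoulli(p_O) (or, when
    ``control_rows`` is given, a verbatim copy of those real presence-absence
    rows).  The treatment block is a *copy* of the control block in which
    only the ``n_perturbed`` randomly chosen columns are replaced by fresh
    Bernoulli(q) draws, with a per-feature likelihood factor sampled from
    ``likelihood_choices``; unperturbed features therefore carry no group
    signal at all.  ``independent_treatment=True`` instead redraws the whole
    treatment block Bernoulli(p_O) (an alternative, noisier reading of the
    design).  Afterwards ``ceil(shuffle_fraction * d)`` random features have
    their column entries permuted across all samples.
    """
    spec = spec or PerturbationSpec()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p_o = np.asarray(baseline_probs, dtype=float)
    d = p_o.size
    if spec.n_perturbed > d:
        raise ValueError(
            f"cannot perturb {spec.n_perturbed} of only {d} features"
        )
    perturbed = rng.choice(d, size=spec.n_perturbed, replace=False)
    p_n = np.full(d, np.nan)
    p_n[perturbed] = rng.choice(spec.likelihood_choices, size=spec.n_perturbed)
    q = perturb_probability(p_o[perturbed], p_n[perturbed])

    if control_rows is not None:
        control = np.asarray(control_rows, dtype=float)
        if control.shape != (spec.n_control, d):
            raise ValueError(
                f"control_rows must be {(spec.n_control, d)}, got {control.shape}"
            )
    else:
        control = (rng.random((spec.n_control, d)) < p_o).astype(float)
    if independent_treatment:
        treatment = (rng.random((spec.n_treatment, d)) < p_o).astype(float)
    else:
        if spec.n_treatment == spec.n_control:
            treatment = control.copy()
        else:
            rows = rng.integers(0, spec.n_control, size=spec.n_treatment)
            treatment = control[rows].copy()
    treatment[:, perturbed] = (
        rng.random((spec.n_treatment, spec.n_perturbed)) < q
    ).astype(float)
    values = np.vstack([control, treatment])

    n_shuffle = int(np.ceil(spec.shuffle_fraction * d))
    shuffled = (
        rng.choice(d, size=n_shuffle, replace=False)
        if n_shuffle > 0
        else np.array([], dtype=int)
    )
    for j in shuffled:
        values[:, j] = values[rng.permutation(values.shape[0]), j]

    truth_mask = np.zeros(d, dtype=bool)
    truth_mask[perturbed] = True
    n_total = spec.n_control + spec.n_treatment
    table = FeatureTable(
        values=values,
        sample_ids=[f"C{i + 1:03d}" for i in range(spec.n_control)]
        + [f"T{i + 1:03d}" for i in range(spec.n_treatment)],
        feature_ids=[f"ASV{j + 1:05d}" for j in range(d)],
        is_binary=True,
    )
    labels = LabelVector(
        labels=["Control"] * spec.n_control + ["Treatment"] * spec.n_treatment,
        classes=["Control", "Treatment"],
    )
    assert table.n_samples == n_total
    return SyntheticDataset(
        table=table,
        labels=labels,
        truth_mask=truth_mask,
        applied_likelihoods=p_n,
        shuffled_features=np.sort(shuffled),
        spec=spec,
    )


# ----------------------------------------------------------------------
def make_two_spirals(
    n_samples: int = 600,
    noise: float = 0.25,
    n_turns: float = 1.75,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two interleaved Archimedean spirals — the classic non-linearity probe."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_per = n_samples // 2
    t = np.sqrt(rng.random(n_per)) * n_turns * 2.0 * np.pi
    dx = t * np.cos(t)
    dy = t * np.sin(t)
    X = np.vstack(
        [
            np.column_stack([dx, dy]),
            np.column_stack([-dx, -dy]),
        ]
    ) + rng.normal(scale=noise, size=(2 * n_per, 2))
    y = np.array(["A"] * n_per + ["B"] * n_per)
    return X, y


def make_concentric_rings(
    n_samples: int = 600,
    noise: float = 0.08,
    factor: float = 0.45,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X, y01 = make_circles(
        n_samples=n_samples,
        noise=noise,
        factor=factor,
        random_state=int(rng.integers(2**31 - 1)),
    )
    return X, np.where(y01 == 0, "A", "B")
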