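"""Seeded, stratified train/test split schedules.

Benchmark repeats use the convention that repeat *i* is split with random
state *i* (the iteration number), so every schedule is reproducible without
storing indices.  Stratification follows scikit-learn's convention: per-class
test counts are the floored ideal with leftover slots assigned to the classes
with the largest fractional remainders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from .table import LabelVector

__all__ = ["SplitSchedule", "stratified_splits"]


@dataclass
class SplitSchedule:
    """A list of (train_indices, test_indices, seed) triples."""

    repeats: list[tuple[np.ndarray, np.ndarray, int]]

    def __len__(self) -> int:
        return len(self.repeats)

    def __iter__(self):
        return iter(self.repeats)


def stratified_splits(
    labels: LabelVector | np.ndarray,
    test_fraction: float = 0.2,
    n_repeats: int = 30,
    seed_policy: str | int = "iteration",
) -> SplitSchedule:
    """Build ``n_repeats`` stratified train/test splits.

    Parameters
    ----------
    seed_policy : "iteration" or int
        "iteration" seeds repeat *i* with *i*; an integer offset ``k`` seeds
        repeat *i* with ``k + i``.
    """
    if not isinstance(labels, LabelVector):
        labels = LabelVector(labels=labels)
    labels.require_supervised()
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    counts = labels.class_counts()
    small = [c for c, n in counts.items() if n < 2]
    if small:
        raise ValueError(f"classes too small to stratify: {small}")
    n = len(labels)
    n_test = int(np.ceil(test_fraction * n))
    if n_test < labels.n_classes:
        raise ValueError(
            f"test fraction {test_fraction} leaves {n_test} test samples, fewer "
            f"than the {labels.n_classes} classes; stratification impossible"
        )
    offset = 0 if seed_policy == "iteration" else int(seed_policy)
    indices = np.arange(n)
    repeats = []
    for i in range(n_repeats):
        seed = offset + i
        train, test = train_test_split(
            indices,
            test_size=test_fraction,
            stratify=labels.labels,
            random_state=seed,
        )
        repeats.append((np.sort(train), np.sort(test), seed))
    return SplitSchedule(repeats=repeats)
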