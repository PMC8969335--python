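"""Sample-by-feature tables and class labels.

The universal data carrier is :class:`FeatureTable`: a dense matrix of
non-negative counts (or 0/1 presences) with rows as samples and columns as
features (ASVs, OTUs, genes, ...).  Amplicon workflows almost always reduce
these tables to presence-absence and drop features seen in fewer than two
samples before modelling; both transforms live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable", "LabelVector"]


def _check_unique(ids, kind: str) -> None:
    seen, dupes = set(), []
    for i in ids:
        if i in seen:
            dupes.append(i)
        seen.add(i)
    if dupes:
        raise ValueError(f"duplicate {kind} identifiers: {sorted(set(dupes))}")


@dataclass
class FeatureTable:
    """A sample-by-feature matrix with aligned identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Non-negative counts, or 0/1 when ``is_binary``.
    sample_ids, feature_ids : sequences of unique strings.
    is_binary : bool
        True once the table has been reduced to presence-absence.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    is_binary: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"row count {n} != number of sample ids {len(self.sample_ids)}"
            )
        if d != len(self.feature_ids):
            raise ValueError(
                f"column count {d} != number of feature ids {len(self.feature_ids)}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("table contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("table contains negative values")
        if self.is_binary and not np.all(np.isin(self.values, (0.0, 1.0))):
            raise ValueError("is_binary set but entries are not all 0/1")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, is_binary: bool = False) -> "FeatureTable":
        return cls(
            values=df.to_numpy(dtype=float),
            sample_ids=[str(i) for i in df.index],
            feature_ids=[str(c) for c in df.columns],
            is_binary=is_binary,
        )

    # ------------------------------------------------------------------
    def to_presence_absence(self) -> "FeatureTable":
        """Binarize counts: 1 wherever the source entry is positive.

        Idempotent; the standard normalization for sparse, compositional
        amplicon tables where read depth is not trusted.
        """
        return FeatureTable(
            values=(self.values > 0).astype(float),
            sample_ids=list(self.sample_ids),
            feature_ids=list(self.feature_ids),
            is_binary=True,
        )

    def filter_min_prevalence(self, min_samples: int = 2) -> "FeatureTable":
        """Keep only features present in at least ``min_samples`` samples.

        Requires a presence-absence table.  Column order is preserved.
        """
        if not self.is_binary:
            raise ValueError(
                "prevalence filtering expects a presence-absence table; "
                "call to_presence_absence() first"
            )
        keep = self.values.sum(axis=0) >= min_samples
        if not np.any(keep):
            raise ValueError(
                f"no feature occurs in >= {min_samples} samples; "
                "reduce the prevalence threshold"
            )
        return FeatureTable(
            values=self.values[:, keep],
            sample_ids=list(self.sample_ids),
            feature_ids=[f for f, k in zip(self.feature_ids, keep) if k],
            is_binary=True,
        )

    def select_features(self, feature_ids) -> "FeatureTable":
        """Subset (and reorder) columns by feature identifier."""
        index = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in index]
        if missing:
            raise KeyError(f"unknown features: {missing[:5]}")
        cols = [index[f] for f in feature_ids]
        return FeatureTable(
            values=self.values[:, cols],
            sample_ids=list(self.sample_ids),
            feature_ids=list(feature_ids),
            is_binary=self.is_binary,
        )


@dataclass
class LabelVector:
    """Class assignments aligned to a table's sample order."""

    labels: np.ndarray
    classes: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray([str(v) for v in np.asarray(self.labels).ravel()])
        if self.classes is None:
            # stable first-appearance order
            seen: dict[str, None] = {}
            for v in self.labels:
                seen.setdefault(v, None)
            self.classes = list(seen)
        else:
            self.classes = [str(c) for c in self.classes]
            unknown = set(self.labels) - set(self.classes)
            if unknown:
                raise ValueError(f"labels outside declared classes: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.classes}

    def require_supervised(self) -> None:
        if self.n_classes < 2:
            raise ValueError("supervised operations need at least two classes")
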