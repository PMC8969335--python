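"""Readers and writers for feature tables and labels.

TSV is the canonical round-trip format: a UTF-8 header row of feature ids and
a first column of sample ids.  Many amplicon tables ship transposed
(features as rows); pass ``transposed=True`` to accept those.  BIOM 2.1
(an HDF5 CSR layout) is supported read-only.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .table import FeatureTable, LabelVector

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_biom",
    "read_labels",
    "write_labels",
]

_SEPS = {"tsv": "\t", "csv": ","}


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("tsv", "txt", "tab"):
        return "tsv"
    if ext == "csv":
        return "csv"
    if ext == "biom":
        return "biom"
    raise ValueError(f"cannot infer table format from extension {ext!r}")


def read_feature_table(
    path: str,
    format: str | None = None,
    transposed: bool = False,
    is_binary: bool = False,
) -> FeatureTable:
    """Read a sample-by-feature table from TSV/CSV/BIOM.

    Parameters
    ----------
    format : {"tsv", "csv", "biom"}, optional
        Inferred from the file extension when omitted.
    transposed : bool
        Set when the file stores features as rows (common for amplicon
        tables); the result is always samples-as-rows.
    """
    fmt = format or _infer_format(path)
    if fmt == "biom":
        return read_biom(path, is_binary=is_binary)
    if fmt not in _SEPS:
        raise ValueError(f"unsupported format {fmt!r}")
    df = pd.read_csv(path, sep=_SEPS[fmt], index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"no samples in {path}")
    if df.shape[1] == 0:
        raise ValueError(f"no features in {path}")
    if transposed:
        df = df.T
    def _unparseable(v) -> bool:
        try:
            float(v)
            return False
        except (TypeError, ValueError):
            return True

    bad = df.map(_unparseable)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at sample {df.index[r]!r}, feature {df.columns[c]!r}"
        )
    return FeatureTable.from_dataframe(df.astype(float), is_binary=is_binary)


def write_feature_table(table: FeatureTable, path: str, format: str | None = None) -> None:
    """Write a table as TSV/CSV (lossless round-trip with read_feature_table)."""
    fmt = format or _infer_format(path)
    if fmt not in _SEPS:
        raise ValueError(f"unsupported output format {fmt!r} (BIOM is read-only)")
    df = table.to_dataframe()
    # counts serialize as integers when they are integral
    if np.all(df.to_numpy() == np.round(df.to_numpy())):
        df = df.astype(int)
    df.to_csv(path, sep=_SEPS[fmt], index_label="sample_id")


def read_biom(path: str, is_binary: bool = False) -> FeatureTable:
    """Read a BIOM 2.1 HDF5 table (observations = features, samples = columns)."""
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as h5:
        feature_ids = [x.decode() for x in h5["observation/ids"][:]]
        sample_ids = [x.decode() for x in h5["sample/ids"][:]]
        grp = h5["observation/matrix"]
        mat = csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(feature_ids), len(sample_ids)),
        )
    return FeatureTable(
        values=np.asarray(mat.T.todense(), dtype=float),
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        is_binary=is_binary,
    )


def read_labels(path: str, table: FeatureTable | None = None) -> LabelVector:
    """Read a two-column (sample_id, class) TSV.

    When ``table`` is given the labels are aligned to its sample order and
    completeness is checked.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("label file must have two columns: sample_id, class")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if table is not None:
        missing = [s for s in table.sample_ids if s not in mapping]
        if missing:
            raise ValueError(f"labels missing for samples: {missing[:5]}")
        return LabelVector(labels=[mapping[s] for s in table.sample_ids])
    return LabelVector(labels=list(df.iloc[:, 1]))


def write_labels(labels: LabelVector, sample_ids, path: str) -> None:
    pd.DataFrame({"sample_id": list(sample_ids), "class": list(labels.labels)}).to_csv(
        path, sep="\t", index=False
    )
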