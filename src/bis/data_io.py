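"""Expression-matrix container and plain-text I/O.

Matrices are always held cells x genes (or bulk samples x genes).  Two
on-disk layouts are supported: a dense delimited table with one header row
and one identifier column, and a Matrix Market coordinate file with
one-identifier-per-line sidecars (the layout 10x-style count exports use).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "ExpressionMatrix",
    "read_dense_table",
    "read_mtx_bundle",
    "align_genes",
    "write_matrix",
]

LAYER_TAGS = ("raw_counts", "normalized", "log_normalized", "imputed")


@dataclass
class ExpressionMatrix:
    """A cells x genes (or samples x genes) nonnegative expression matrix.

    Parameters
    ----------
    values
        2-D float array, finite and >= 0.
    row_ids
        Cell barcodes or bulk sample names; unique, one per row.
    col_ids
        Gene identifiers; unique, one per column.
    layer_tag
        One of ``raw_counts``, ``normalized``, ``log_normalized``, ``imputed``.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    layer_tag: str = "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.layer_tag not in LAYER_TAGS:
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")
        n, m = self.values.shape
        if len(self.row_ids) != n or len(self.col_ids) != m:
            raise ValueError(
                f"identifier lengths ({len(self.row_ids)}, {len(self.col_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        for name, ids in (("row", self.row_ids), ("column", self.col_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("values contain negative entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, layer_tag: str | None = None) -> "ExpressionMatrix":
        """Copy carrying new values (same identifiers)."""
        return ExpressionMatrix(
            values=np.asarray(values, dtype=float),
            row_ids=list(self.row_ids),
            col_ids=list(self.col_ids),
            layer_tag=layer_tag if layer_tag is not None else self.layer_tag,
        )

    def subset(self, rows: np.ndarray | None = None, cols: np.ndarray | None = None) -> "ExpressionMatrix":
        """Positional subset along rows and/or columns."""
        vals = self.values
        row_ids, col_ids = self.row_ids, self.col_ids
        if rows is not None:
            rows = np.asarray(rows)
            vals = vals[rows, :]
            row_ids = [self.row_ids[i] for i in rows]
        if cols is not None:
            cols = np.asarray(cols)
            vals = vals[:, cols]
            col_ids = [self.col_ids[j] for j in cols]
        return ExpressionMatrix(vals, row_ids, col_ids, self.layer_tag)


def _validated_orientation(orientation: str) -> str:
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValueError(f"unknown orientation {orientation!r}")
    return orientation


def read_dense_table(path: str | os.PathLike, orientation: str = "cells_by_genes") -> ExpressionMatrix:
    """Read a dense TSV/CSV table into a cells x genes ExpressionMatrix.

    The first row holds column identifiers and the first column row
    identifiers.  ``orientation='genes_by_cells'`` transposes on read so the
    result is always cells x genes.  The delimiter is sniffed from the
    extension (``.csv`` -> comma, anything else -> tab).
    """
    _validated_orientation(orientation)
    sep = "," if str(path).endswith(".csv") else "\t"
    with open(path) as fh:
        header_ids = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header_ids)) != len(header_ids):
        raise ValueError(f"duplicate column identifiers in {path}")
    df = pd.read_csv(path, sep=sep, index_col=0, header=0, na_filter=False)
    body = df.to_numpy(dtype=object)
    try:
        values = body.astype(float)
    except (TypeError, ValueError):
        bad = _first_non_numeric(df)
        raise ValueError(
            f"non-numeric entry at row {bad[0]!r}, column {bad[1]!r} in {path}"
        ) from None
    if not np.all(np.isfinite(values)):
        bad = _first_non_finite(df, values)
        raise ValueError(
            f"non-finite entry at row {bad[0]!r}, column {bad[1]!r} in {path}"
        )
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if orientation == "genes_by_cells":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(values, row_ids, col_ids, layer_tag="raw_counts")


def _first_non_numeric(df: pd.DataFrame) -> tuple[str, str]:
    for i, row in enumerate(df.index):
        for j, col in enumerate(df.columns):
            try:
                float(df.iat[i, j])
            except (TypeError, ValueError):
                return str(row), str(col)
    return "?", "?"


def _first_non_finite(df: pd.DataFrame, values: np.ndarray) -> tuple[str, str]:
    i, j = np.argwhere(~np.isfinite(values))[0]
    return str(df.index[i]), str(df.columns[j])


def _read_id_file(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]


def read_mtx_bundle(
    matrix_path: str | os.PathLike,
    row_ids_path: str | os.PathLike,
    col_ids_path: str | os.PathLike,
    orientation: str = "genes_by_cells",
) -> ExpressionMatrix:
    """Read a Matrix Market coordinate file plus identifier sidecars.

    ``row_ids_path``/``col_ids_path`` list identifiers for the matrix file's
    own rows/columns (before any transposition).  Unlisted coordinates are
    zero.  With the 10x convention (genes x cells on disk) pass
    ``orientation='genes_by_cells'`` to obtain a cells x genes matrix.
    """
    _validated_orientation(orientation)
    mat = spio.mmread(matrix_path)
    if sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    row_ids = _read_id_file(row_ids_path)
    col_ids = _read_id_file(col_ids_path)
    if len(row_ids) != mat.shape[0] or len(col_ids) != mat.shape[1]:
        raise ValueError(
            f"sidecar lengths ({len(row_ids)}, {len(col_ids)}) do not match "
            f"matrix dimensions {mat.shape}"
        )
    if orientation == "genes_by_cells":
        mat = mat.T
        row_ids, col_ids = col_ids, row_ids
    return ExpressionMatrix(mat, row_ids, col_ids, layer_tag="raw_counts")


def align_genes(sc: ExpressionMatrix, bulk: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their common genes.

    The surviving genes keep the single-cell matrix's original order, so the
    two outputs have identical column order.  Matching is exact,
    case-sensitive string equality.
    """
    bulk_set = set(bulk.col_ids)
    shared = [g for g in sc.col_ids if g in bulk_set]
    if not shared:
        raise ValueError("gene intersection is empty: incompatible feature spaces")
    bulk_pos = {g: j for j, g in enumerate(bulk.col_ids)}
    sc_idx = np.array([j for j, g in enumerate(sc.col_ids) if g in bulk_set])
    bulk_idx = np.array([bulk_pos[g] for g in shared])
    return sc.subset(cols=sc_idx), bulk.subset(cols=bulk_idx)


def write_matrix(m: ExpressionMatrix, path: str | os.PathLike, format: str = "tsv") -> None:
    """Write an ExpressionMatrix as a dense table or an MTX bundle.

    ``format='tsv'`` writes a single delimited table readable by
    :func:`read_dense_table`.  ``format='mtx'`` writes ``path`` as a
    Matrix Market coordinate file in cells x genes orientation plus
    ``<path>.rows`` and ``<path>.cols`` identifier sidecars readable by
    :func:`read_mtx_bundle` with ``orientation='cells_by_genes'``.
    """
    if format == "tsv":
        df = pd.DataFrame(m.values, index=m.row_ids, columns=m.col_ids)
        df.to_csv(path, sep="\t", float_format="%.10g")
    elif format == "mtx":
        spio.mmwrite(str(path), sparse.coo_matrix(m.values))
        with open(f"{path}.rows", "w") as fh:
            fh.write("\n".join(m.row_ids) + "\n")
        with open(f"{path}.cols", "w") as fh:
            fh.write("\n".join(m.col_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
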