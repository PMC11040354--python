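"""Quality-control filtering and normalization of raw counts.

The pipeline applied to single-cell counts before modelling is: drop cells
expressing fewer than 200 genes, drop genes expressed in fewer than 3 of the
remaining cells, rescale each cell to a common total, then log(1 + x).
Bulk tables skip the QC step (they have no empty-droplet failure mode) but
receive the same normalization and log transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix

__all__ = ["QCThresholds", "filter_qc", "normalize_total", "log1p_transform", "preprocess_pipeline"]


@dataclass(frozen=True)
class QCThresholds:
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ValueError("QC thresholds must be nonnegative")


def filter_qc(
    raw: ExpressionMatrix,
    t: QCThresholds = QCThresholds(),
    apply_to: str = "single_cell",
) -> ExpressionMatrix:
    """Filter low-complexity cells, then rarely-observed genes.

    A cell is kept iff it has at least ``min_genes_per_cell`` strictly
    positive entries; a gene is then kept iff it is positive in at least
    ``min_cells_per_gene`` of the *retained* cells.  One pass each, cells
    first.  Bulk matrices pass through unchanged.
    """
    if apply_to not in ("single_cell", "bulk"):
        raise ValueError(f"unknown apply_to {apply_to!r}")
    if raw.layer_tag != "raw_counts":
        raise ValueError("filter_qc expects raw counts")
    if apply_to == "bulk":
        return raw
    expressed = raw.values > 0
    keep_cells = expressed.sum(axis=1) >= t.min_genes_per_cell
    if not keep_cells.any():
        raise ValueError("QC removed every cell")
    keep_genes = expressed[keep_cells].sum(axis=0) >= t.min_cells_per_gene
    if not keep_genes.any():
        raise ValueError("QC removed every gene")
    return raw.subset(rows=np.flatnonzero(keep_cells), cols=np.flatnonzero(keep_genes))


def normalize_total(raw: ExpressionMatrix, target_sum: float | str = "auto") -> ExpressionMatrix:
    """Scale each row to a common total count.

    With ``target_sum='auto'`` the target is the median of the pre-scaling
    per-row totals (so a typical cell is left roughly unchanged).  Zero-total
    rows are an error; QC should have removed them.
    """
    if raw.layer_tag != "raw_counts":
        raise ValueError("normalize_total expects raw counts")
    totals = raw.values.sum(axis=1)
    if np.any(totals <= 0):
        bad = raw.row_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"row {bad!r} has zero total count; filter before normalizing")
    if target_sum == "auto":
        target = float(np.median(totals))
    else:
        target = float(target_sum)
        if target <= 0:
            raise ValueError("target_sum must be positive")
    scaled = raw.values * (target / totals)[:, None]
    return raw.with_values(scaled, layer_tag="normalized")


def log1p_transform(x: ExpressionMatrix) -> ExpressionMatrix:
    """Apply v -> ln(1 + v) elementwise."""
    if x.layer_tag != "normalized":
        raise ValueError("log1p_transform expects a normalized matrix")
    if np.any(x.values < 0):
        raise ValueError("negative values cannot be log1p-transformed")
    return x.with_values(np.log1p(x.values), layer_tag="log_normalized")


def preprocess_pipeline(
    raw: ExpressionMatrix,
    t: QCThresholds = QCThresholds(),
    apply_to: str = "single_cell",
    target_sum: float | str = "auto",
) -> ExpressionMatrix:
    """QC (single-cell only) -> total-count normalization -> log1p."""
    return log1p_transform(normalize_total(filter_qc(raw, t, apply_to), target_sum))
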