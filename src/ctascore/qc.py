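"""Cell-level quality-control filters.

Two filters are applied before scoring: cells whose mitochondrial
fraction exceeds a maximum (strictly greater is removed) and cells whose
unique-feature count lies outside an inclusive range are discarded.
Defaults follow common mouse scRNA-seq practice: remove cells with more
than 25% mitochondrial reads, keep cells detecting 200-5,000 genes.

Gene-level filtering is available but explicitly opt-in
(``drop_unexpressed_genes`` / ``min_cells_per_gene``): upstream toolkits
often apply an implicit minimum-cells-per-gene cut, so gene dropping here
is never silent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix
from .errors import InputError


@dataclass
class QCParams:
    """Thresholds for the cell-level QC filters.

    Attributes
    ----------
    mito_max_fraction
        Cells with mitochondrial fraction strictly above this are removed.
    min_features, max_features
        Inclusive bounds on the per-cell unique-feature (detected gene) count.
    mito_prefix
        Gene-id prefix identifying mitochondrial genes ("mt-" for mouse,
        "MT-" for human). Matching is case-sensitive.
    drop_unexpressed_genes
        If true, genes expressed in fewer than ``min_cells_per_gene`` kept
        cells are removed after cell filtering. Off by default.
    """

    mito_max_fraction: float = 0.25
    min_features: int = 200
    max_features: int = 5000
    mito_prefix: str = "mt-"
    drop_unexpressed_genes: bool = False
    min_cells_per_gene: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.mito_max_fraction <= 1.0:
            raise InputError("mito_max_fraction must be in [0, 1]")
        if self.min_features < 0 or self.max_features < 0:
            raise InputError("feature-count bounds must be non-negative")
        if self.min_features > self.max_features:
            raise InputError("min_features must not exceed max_features")


@dataclass
class QCReport:
    """Per-cell diagnostics and counts from one :func:`qc_filter` run."""

    n_cells_in: int
    n_cells_kept: int
    n_removed_mito: int
    n_removed_features: int
    n_genes_in: int
    n_genes_kept: int
    per_cell_mito_fraction: dict[str, float] = field(repr=False)
    per_cell_feature_count: dict[str, int] = field(repr=False)
    kept_cells: list[str] = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_kept": self.n_cells_kept,
            "n_removed_mito": self.n_removed_mito,
            "n_removed_features": self.n_removed_features,
            "n_genes_in": self.n_genes_in,
            "n_genes_kept": self.n_genes_kept,
            "per_cell_mito_fraction": self.per_cell_mito_fraction,
            "per_cell_feature_count": self.per_cell_feature_count,
        }


def mito_fraction(expr: ExpressionMatrix, mito_prefix: str = "mt-") -> dict[str, float]:
    """Fraction of each cell's total expression carried by mitochondrial genes.

    A cell with zero total expression gets fraction 0 (with a warning);
    if no gene matches the prefix every fraction is 0.
    """
    if expr.n_cells == 0:
        raise InputError("expression matrix has no cells")
    is_mito = np.array([str(g).startswith(mito_prefix) for g in expr.gene_ids])
    totals = expr.values.sum(axis=0)
    mito_totals = expr.values[is_mito].sum(axis=0) if is_mito.any() else np.zeros(expr.n_cells)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cell(s) with zero total expression", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(zero, 0.0, mito_totals / np.where(zero, 1.0, totals))
    return dict(zip(expr.cell_ids, frac.astype(float)))


def feature_count(expr: ExpressionMatrix) -> dict[str, int]:
    """Number of genes detected (expression strictly > 0) per cell."""
    counts = (expr.values > 0).sum(axis=0)
    return {c: int(n) for c, n in zip(expr.cell_ids, counts)}


def qc_filter(expr: ExpressionMatrix, params: QCParams | None = None) -> tuple[ExpressionMatrix, QCReport]:
    """Apply the cell-level filters and return the kept submatrix plus a report.

    A cell is kept iff its mitochondrial fraction is <= ``mito_max_fraction``
    and its feature count lies within ``[min_features, max_features]``
    (both bounds inclusive). An empty result is a warning, not an error.
    """
    params = params or QCParams()
    mito = mito_fraction(expr, params.mito_prefix)
    feats = feature_count(expr)
    mito_arr = np.array([mito[c] for c in expr.cell_ids])
    feat_arr = np.array([feats[c] for c in expr.cell_ids])

    fail_mito = mito_arr > params.mito_max_fraction
    fail_feat = (feat_arr < params.min_features) | (feat_arr > params.max_features)
    keep = ~(fail_mito | fail_feat)

    kept = expr.subset_cells(keep)
    n_genes_kept = kept.n_genes
    if params.drop_unexpressed_genes:
        cells_per_gene = (kept.values > 0).sum(axis=1)
        kept = kept.subset_genes(cells_per_gene >= params.min_cells_per_gene)
        n_genes_kept = kept.n_genes
    if kept.n_cells == 0:
        warnings.warn("QC filter removed every cell", stacklevel=2)

    report = QCReport(
        n_cells_in=expr.n_cells,
        n_cells_kept=int(keep.sum()),
        n_removed_mito=int(fail_mito.sum()),
        n_removed_features=int(fail_feat.sum()),
        n_genes_in=expr.n_genes,
        n_genes_kept=n_genes_kept,
        per_cell_mito_fraction=mito,
        per_cell_feature_count=feats,
        kept_cells=[c for c, k in zip(expr.cell_ids, keep) if k],
    )
    return kept, report
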