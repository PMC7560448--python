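"""The Cell Type Activity (CTA) score.

Given a genes x cells expression matrix, a partition of cells into K
clusters, and a marker list per cell type, the score for one cell type
is computed in four steps, repeated once per cell type:

1. Tabulate the cluster **median** expression of each of the type's N
   markers, giving an N x K matrix, and normalize each row to sum to
   unity (row i becomes ``p_i1 .. p_iK``).
2. Weight each marker by an inverted Gini impurity,

       W_i = 1 + sum_k p_ik**2,

   so a marker expressed specifically in a single cluster gets the
   maximal weight 2, and a marker spread uniformly over clusters gets
   the minimal weight 1 + 1/K.
3. Score each cluster with the weighted **mean** marker expression,

       S_k = sum_i Ebar_ik * W_i / N**3,

   where ``Ebar_ik`` is the average expression of marker i over the
   cells of cluster k.
4. Convert the scores to a probability profile over clusters by
   normalizing them to sum to one.

The N**3 denominator is a per-cell-type constant, so it cancels in
step 4; annotations are invariant to that convention (and to any global
rescaling of the expression values). Raw scores are reported as well but
depend on the denominator convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import ClusterAssignment, ExpressionMatrix, MarkerCatalog
from .errors import InputError

__all__ = [
    "ClusterProfile",
    "CTAScoreVector",
    "CTAMatrix",
    "build_cluster_profile",
    "row_normalize",
    "gini_weight",
    "cta_score",
    "compute_cta_matrix",
]


@dataclass
class ClusterProfile:
    """Per-cluster summary of one cell type's markers.

    ``median_raw`` holds cluster medians (drives the specificity weights),
    ``mean_expr`` holds cluster means (drives the score magnitude), and
    ``P`` is the row-normalized median matrix.
    """

    marker_ids: list[str]
    cluster_labels: list[str]
    median_raw: np.ndarray
    P: np.ndarray
    mean_expr: np.ndarray
    dropped_markers: list[str] = field(default_factory=list)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


@dataclass
class CTAScoreVector:
    """One cell type's raw and normalized scores over the K clusters."""

    cell_type: str
    cluster_labels: list[str]
    raw: np.ndarray
    normalized: np.ndarray


@dataclass
class CTAMatrix:
    """C x K matrix of normalized CTA scores; rows are cell types.

    Each row is a probability profile over clusters (sums to one).
    ``raw`` carries the unnormalized scores when available; ``excluded``
    lists cell types dropped because none of their markers were found.
    """

    cell_types: list[str]
    cluster_labels: list[str]
    scores: np.ndarray
    raw: np.ndarray | None = None
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.cell_types), len(self.cluster_labels)):
            raise InputError(
                f"score grid {self.scores.shape} does not match "
                f"{len(self.cell_types)} types x {len(self.cluster_labels)} clusters"
            )

    def row(self, cell_type: str) -> np.ndarray:
        try:
            return self.scores[self.cell_types.index(cell_type)]
        except ValueError:
            raise InputError(f"unknown cell type {cell_type!r}") from None


def _cluster_cell_columns(
    expr: ExpressionMatrix, clusters: ClusterAssignment
) -> list[np.ndarray]:
    """Column indices of each cluster's cells, in canonical cluster order."""
    cell_idx = expr.cell_index()
    missing = [c for c in clusters.cell_to_cluster if c not in cell_idx]
    if len(missing) == len(clusters.cell_to_cluster):
        raise InputError("no cell of the cluster assignment is present in the matrix")
    if missing:
        warnings.warn(
            f"{len(missing)} assigned cell(s) absent from the expression matrix",
            stacklevel=3,
        )
    cols = []
    for label in clusters.cluster_labels:
        idx = np.array(
            [cell_idx[c] for c in clusters.cell_to_cluster
             if clusters.cell_to_cluster[c] == label and c in cell_idx],
            dtype=int,
        )
        if idx.size == 0:
            raise InputError(f"cluster {label!r} has no cells in the expression matrix")
        cols.append(idx)
    return cols


def build_cluster_profile(
    expr: ExpressionMatrix,
    clusters: ClusterAssignment,
    markers: list[str],
) -> ClusterProfile:
    """Summarize marker expression per cluster (step 1 of the score).

    Markers absent from the matrix are dropped (recorded in
    ``dropped_markers``) and N is reduced accordingly; an even-count
    median is the midpoint of the two central values.
    """
    gene_idx = expr.gene_index()
    found = [m for m in markers if m in gene_idx]
    dropped = [m for m in markers if m not in gene_idx]
    if not found:
        raise InputError(f"none of the markers are present in the matrix: {list(markers)}")
    if dropped:
        warnings.warn(f"markers absent from the matrix, dropped: {dropped}", stacklevel=2)

    rows = np.array([gene_idx[m] for m in found], dtype=int)
    cols_per_cluster = _cluster_cell_columns(expr, clusters)
    n, k = len(found), len(cols_per_cluster)
    median_raw = np.empty((n, k))
    mean_expr = np.empty((n, k))
    for j, cols in enumerate(cols_per_cluster):
        block = expr.values[np.ix_(rows, cols)]
        median_raw[:, j] = np.median(block, axis=1)
        mean_expr[:, j] = block.mean(axis=1)
    return ClusterProfile(
        marker_ids=found,
        cluster_labels=list(clusters.cluster_labels),
        median_raw=median_raw,
        P=row_normalize(median_raw),
        mean_expr=mean_expr,
        dropped_markers=dropped,
    )


def row_normalize(median_raw: np.ndarray) -> np.ndarray:
    """Normalize each row to sum to unity; an all-zero row becomes uniform.

    The uniform convention is harmless: a marker with zero median
    everywhere has the least informative weight, and its mean-expression
    contribution is typically negligible anyway.
    """
    m = np.asarray(median_raw, dtype=float)
    if m.ndim != 2:
        raise InputError("expected a 2-D N x K grid")
    if m.size and np.min(m) < 0:
        raise InputError("negative entries are not allowed in the profile matrix")
    sums = m.sum(axis=1, keepdims=True)
    k = m.shape[1]
    out = np.where(sums > 0, m / np.where(sums > 0, sums, 1.0), 1.0 / k)
    return out


def gini_weight(P: np.ndarray) -> np.ndarray:
    """Inverted-Gini specificity weight per marker: ``w_i = 1 + sum_k p_ik**2``.

    Rows of ``P`` must be probability profiles. The weight ranges from
    1 + 1/K (uniform row) to 2 (one-hot row).
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise InputError("expected a 2-D N x K grid")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise InputError("each row of P must sum to 1")
    # fixed accumulation order (ascending k) for bit-stable output
    return 1.0 + np.add.reduce(P * P, axis=1)


def cta_score(profile: ClusterProfile, w: np.ndarray) -> CTAScoreVector:
    """Weighted mean-expression score per cluster, then normalized to sum to 1.

    If every raw score is zero the normalized profile falls back to the
    uniform distribution with a warning.
    """
    w = np.asarray(w, dtype=float)
    n, k = profile.mean_expr.shape
    if w.shape != (n,):
        raise InputError(f"weight vector length {w.shape} does not match N={n}")
    raw = (profile.mean_expr * w[:, None]).sum(axis=0) / float(n) ** 3
    total = raw.sum()
    if total > 0:
        normalized = raw / total
    else:
        warnings.warn("all raw scores are zero; normalized profile set to uniform", stacklevel=2)
        normalized = np.full(k, 1.0 / k)
    return CTAScoreVector(
        cell_type="",
        cluster_labels=list(profile.cluster_labels),
        raw=raw,
        normalized=normalized,
    )


def score_cell_type(
    expr: ExpressionMatrix,
    clusters: ClusterAssignment,
    markers: list[str],
    cell_type: str = "",
) -> CTAScoreVector:
    """Run the four steps for a single cell type."""
    profile = build_cluster_profile(expr, clusters, markers)
    vec = cta_score(profile, gini_weight(profile.P))
    vec.cell_type = cell_type
    return vec


def compute_cta_matrix(
    expr: ExpressionMatrix,
    clusters: ClusterAssignment,
    catalog: MarkerCatalog,
) -> CTAMatrix:
    """Score every cell type of the catalog, yielding the C x K CTA matrix.

    Each cell type is scored independently with its own marker count N
    (after dropping markers absent from the matrix); markers shared by
    several types contribute to each. A cell type with no marker found
    is excluded from the matrix and listed in ``excluded``.
    """
    gene_ids = set(expr.gene_ids)
    kept_types: list[str] = []
    rows_norm: list[np.ndarray] = []
    rows_raw: list[np.ndarray] = []
    excluded: list[str] = []
    for cell_type in catalog.cell_types:
        found = [m for m in catalog.entries[cell_type] if m in gene_ids]
        if not found:
            warnings.warn(
                f"cell type {cell_type!r} excluded: no marker present in the matrix",
                stacklevel=2,
            )
            excluded.append(cell_type)
            continue
        vec = score_cell_type(expr, clusters, catalog.entries[cell_type], cell_type)
        kept_types.append(cell_type)
        rows_norm.append(vec.normalized)
        rows_raw.append(vec.raw)
    if not kept_types:
        raise InputError("no cell type retains any marker present in the matrix")
    return CTAMatrix(
        cell_types=kept_types,
        cluster_labels=list(clusters.cluster_labels),
        scores=np.vstack(rows_norm),
        raw=np.vstack(rows_raw),
        excluded=excluded,
    )
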