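"""Turn a CTA matrix into cluster -> cell-type annotations.

The method is semi-automatic: per cell type the user inspects the
cumulative distribution of the normalized scores over clusters (both the
empirical curve and a normal CDF fitted by moments are provided) and
chooses a cutoff; clusters scoring strictly above a type's cutoff are
annotated with it. A single default cutoff supports non-interactive
pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ClusterAssignment, ExpressionMatrix
from .core import CTAMatrix
from .errors import InputError

UNASSIGNED = "unassigned"


@dataclass
class CutoffSpec:
    """Per-cell-type score cutoffs with a fallback default.

    All cutoffs live on the normalized-score scale, i.e. in [0, 1].
    """

    per_type: dict[str, float] = field(default_factory=dict)
    default_cutoff: float = 0.5

    def __post_init__(self) -> None:
        for name, c in {**self.per_type, "default": self.default_cutoff}.items():
            if not 0.0 <= c <= 1.0:
                raise InputError(f"cutoff for {name!r} must be in [0, 1], got {c}")

    def cutoff(self, cell_type: str) -> float:
        return self.per_type.get(cell_type, self.default_cutoff)


@dataclass
class ScoreDistribution:
    """Empirical CDF of one score row plus moment-fitted normal parameters."""

    scores: np.ndarray       # sorted ascending
    ecdf: np.ndarray         # rank/K for each sorted score
    mean: float
    sd: float | None


@dataclass
class AnnotationResult:
    """Final cluster -> cell-type labels with scores and conflict records."""

    cluster_to_type: dict[str, str]
    cluster_to_score: dict[str, float]
    conflicts: list[tuple[str, list[tuple[str, float]]]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": list(self.cluster_to_type),
                "cell_type": list(self.cluster_to_type.values()),
                "score": [self.cluster_to_score[k] for k in self.cluster_to_type],
            }
        )


def score_distribution(row: np.ndarray) -> ScoreDistribution:
    """Empirical CDF points and normal moments for one cell type's score row.

    With a single cluster the standard deviation is undefined; only the
    empirical point is returned (with a warning).
    """
    row = np.asarray(row, dtype=float)
    if row.ndim != 1 or row.size == 0:
        raise InputError("expected a non-empty 1-D score row")
    order = np.sort(row)
    k = row.size
    ecdf = np.arange(1, k + 1) / k
    if k < 2:
        warnings.warn("single-cluster row: standard deviation undefined", stacklevel=2)
        return ScoreDistribution(order, ecdf, float(row[0]), None)
    return ScoreDistribution(order, ecdf, float(row.mean()), float(row.std(ddof=0)))


def assign_types(m: CTAMatrix, cutoffs: CutoffSpec | None = None) -> AnnotationResult:
    """Annotate each cluster with the best cell type scoring above its cutoff.

    For cluster k the candidates are the cell types whose normalized
    score is strictly above that type's cutoff. No candidate leaves the
    cluster ``unassigned``; several candidates are resolved by the
    highest normalized score (recorded in ``conflicts``), exact ties by
    catalog order.
    """
    cutoffs = cutoffs or CutoffSpec()
    unknown = sorted(set(cutoffs.per_type) - set(m.cell_types) - set(m.excluded))
    if unknown:
        raise InputError(f"cutoffs reference unknown cell types: {unknown}")

    cluster_to_type: dict[str, str] = {}
    cluster_to_score: dict[str, float] = {}
    conflicts: list[tuple[str, list[tuple[str, float]]]] = []
    for j, cluster in enumerate(m.cluster_labels):
        candidates = [
            (ct, float(m.scores[i, j]))
            for i, ct in enumerate(m.cell_types)
            if m.scores[i, j] > cutoffs.cutoff(ct)
        ]
        if not candidates:
            cluster_to_type[cluster] = UNASSIGNED
            cluster_to_score[cluster] = float("nan")
            continue
        # stable max: catalog order breaks exact ties
        winner = max(candidates, key=lambda t: t[1])
        if len(candidates) > 1:
            conflicts.append((cluster, candidates))
        cluster_to_type[cluster] = winner[0]
        cluster_to_score[cluster] = winner[1]
    return AnnotationResult(cluster_to_type, cluster_to_score, conflicts)


@dataclass
class AnnotationSummary:
    """Per-type (cell count, expressed-gene count) table with an unassigned footer."""

    table: pd.DataFrame
    n_unassigned_clusters: int
    n_unassigned_cells: int


def summarize_annotation(
    result: AnnotationResult,
    clusters: ClusterAssignment,
    expr: ExpressionMatrix,
) -> AnnotationSummary:
    """Count member cells and expressed genes for each annotated cell type.

    Clusters sharing a cell type are pooled before counting; a gene
    counts as expressed for a type when it is > 0 in at least one of the
    type's cells. Unassigned clusters are excluded from the table but
    reported in the footer counts.
    """
    cell_idx = expr.cell_index()
    type_to_clusters: dict[str, list[str]] = {}
    for cluster, cell_type in result.cluster_to_type.items():
        type_to_clusters.setdefault(cell_type, []).append(cluster)

    rows = []
    n_un_clusters = 0
    n_un_cells = 0
    for cell_type, members in type_to_clusters.items():
        cells = [
            c for c, lab in clusters.cell_to_cluster.items()
            if lab in members and c in cell_idx
        ]
        if cell_type == UNASSIGNED:
            n_un_clusters = len(members)
            n_un_cells = len(cells)
            continue
        cols = np.array([cell_idx[c] for c in cells], dtype=int)
        n_genes = int((expr.values[:, cols] > 0).any(axis=1).sum()) if cols.size else 0
        rows.append((cell_type, len(cells), n_genes))
    table = pd.DataFrame(rows, columns=["cell_type", "n_cells", "n_genes"])
    table = table.sort_values("n_cells", ascending=False, kind="stable").reset_index(drop=True)
    return AnnotationSummary(table, n_un_clusters, n_un_cells)


def write_annotation(result: AnnotationResult, path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_annotation(path) -> AnnotationResult:
    df = pd.read_csv(path, sep="\t", dtype={"cluster": str, "cell_type": str})
    return AnnotationResult(
        cluster_to_type=dict(zip(df["cluster"], df["cell_type"])),
        cluster_to_score=dict(zip(df["cluster"], df["score"].astype(float))),
    )


def plot_score_cdf(row: np.ndarray, cell_type: str, path) -> None:
    """Write the empirical CDF of one score row with a fitted normal overlay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import norm

    dist = score_distribution(np.asarray(row, dtype=float))
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.step(dist.scores, dist.ecdf, where="post", label="empirical CDF")
    if dist.sd is not None and dist.sd > 0:
        xs = np.linspace(float(dist.scores[0]), float(dist.scores[-1]), 200)
        ax.plot(xs, norm.cdf(xs, dist.mean, dist.sd), "--", label="normal fit")
    ax.set_xlabel("normalized CTA score")
    ax.set_ylabel("cumulative fraction of clusters")
    ax.set_title(cell_type)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
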