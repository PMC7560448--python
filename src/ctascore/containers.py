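"""In-memory containers for expression data, cluster labels and marker sets.

The containers are deliberately thin: a genes x cells matrix with string
identifiers, a cell -> cluster mapping, and an ordered catalog of marker
gene lists. They validate their own invariants on construction so that
downstream numerics can assume well-formed input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        seen: set[str] = set()
        dups = sorted({x for x in ids if x in seen or seen.add(x)})  # type: ignore[func-returns-value]
        raise InputError(f"duplicate {what}: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """Genes x cells non-negative expression matrix.

    Values are unit-agnostic (raw or log-normalized counts); negative
    values are rejected because the scoring method row-normalizes
    expression profiles to unity, which is undefined for signed data.

    Parameters
    ----------
    gene_ids
        Unique gene symbols, one per row.
    cell_ids
        Unique cell barcodes, one per column.
    values
        Dense ``(n_genes, n_cells)`` array of non-negative reals.
    """

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InputError("expression values must be a 2-D genes x cells grid")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise InputError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        if self.values.size and np.min(self.values) < 0:
            raise InputError("negative expression values are not supported")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell_index(self) -> dict[str, int]:
        return {c: j for j, c in enumerate(self.cell_ids)}

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_cells(self, keep: np.ndarray) -> "ExpressionMatrix":
        """Return a new matrix restricted to a boolean or index cell mask."""
        return ExpressionMatrix(self.gene_ids, self.cell_ids[keep], self.values[:, keep])

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(self.gene_ids[keep], self.cell_ids, self.values[keep, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.cell_ids))


@dataclass
class ClusterAssignment:
    """Mapping of each cell to one of K cluster labels.

    Labels are opaque strings; ``cluster_labels`` is ordered by first
    appearance in the input and that order is canonical for all
    downstream matrices.
    """

    cell_to_cluster: dict[str, str]
    cluster_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cell_to_cluster = {str(c): str(k) for c, k in self.cell_to_cluster.items()}
        if not self.cluster_labels:
            seen: list[str] = []
            for lab in self.cell_to_cluster.values():
                if lab not in seen:
                    seen.append(lab)
            self.cluster_labels = seen
        else:
            self.cluster_labels = [str(x) for x in self.cluster_labels]
        if not self.cell_to_cluster:
            raise InputError("cluster assignment is empty")
        present = set(self.cell_to_cluster.values())
        missing = [k for k in self.cluster_labels if k not in present]
        if missing:
            raise InputError(f"cluster labels with no member cells: {missing}")
        extra = sorted(present - set(self.cluster_labels))
        if extra:
            raise InputError(f"cells assigned to undeclared clusters: {extra}")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels)

    def members(self, label: str) -> list[str]:
        return [c for c, k in self.cell_to_cluster.items() if k == label]


@dataclass
class MarkerCatalog:
    """Ordered catalog of cell types, each with its marker gene list."""

    entries: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise InputError("marker catalog is empty")
        for cell_type, markers in self.entries.items():
            if not markers:
                raise InputError(f"cell type {cell_type!r} has no markers")
            if len(markers) != len(set(markers)):
                seen: set[str] = set()
                dups = [m for m in markers if m in seen or seen.add(m)]  # type: ignore[func-returns-value]
                raise InputError(
                    f"duplicate markers for cell type {cell_type!r}: {sorted(set(dups))}"
                )

    @property
    def cell_types(self) -> list[str]:
        return list(self.entries)

    @property
    def n_types(self) -> int:
        return len(self.entries)

    def markers_found(self, gene_ids: set[str], cell_type: str) -> tuple[list[str], list[str]]:
        """Split one type's markers into (present, absent) w.r.t. a gene universe.

        Matching is exact and case-sensitive: silent case-folding can hide
        species mix-ups (mouse ``mt-`` vs human ``MT-`` prefixes).
        """
        found = [m for m in self.entries[cell_type] if m in gene_ids]
        dropped = [m for m in self.entries[cell_type] if m not in gene_ids]
        if dropped:
            warnings.warn(
                f"cell type {cell_type!r}: {len(dropped)} marker(s) absent "
                f"from the expression matrix: {dropped}",
                stacklevel=2,
            )
        return found, dropped
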