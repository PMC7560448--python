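"""Readers and writers for the external file formats.

Expression matrices come in as 10x-style MatrixMarket triplets
(``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv``, optionally
gzipped) or as dense TSV; cluster tables and cell-type activity (CTA)
matrices are TSV; marker catalogs are two-column CSV or GMT gene sets.
MatrixMarket parsing is delegated to :func:`scipy.io.mmread`.
"""

from __future__ import annotations

import csv
import gzip
import logging
import warnings
from pathlib import Path
from typing import IO, TYPE_CHECKING

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import ClusterAssignment, ExpressionMatrix, MarkerCatalog
from .errors import FormatError, InputError

if TYPE_CHECKING:  # pragma: no cover
    from .core import CTAMatrix

log = logging.getLogger(__name__)

# Conventional header names used to detect an optional header row.
_CELL_HEADERS = {"cell", "cell_id", "barcode", "cells"}
_CLUSTER_HEADERS = {"cluster", "cluster_id", "cluster_label", "label", "seurat_clusters"}
_TYPE_HEADERS = {"cell_type", "celltype", "type"}
_GENE_HEADERS = {"gene", "gene_id", "marker", "symbol"}


def _find_sidecar(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise InputError(f"missing file {stem}[.gz] in {dir_path}")


def _open_text(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_lines(path: Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def deduplicate_ids(ids: list[str]) -> list[str]:
    """Make identifiers unique by suffixing ``.1``, ``.2``, ... in file order."""
    counts: dict[str, int] = {}
    out = []
    for x in ids:
        n = counts.get(x, 0)
        out.append(x if n == 0 else f"{x}.{n}")
        counts[x] = n + 1
    return out


def read_10x_mtx(dir_path: str | Path) -> ExpressionMatrix:
    """Read a 10x-style MatrixMarket directory into an :class:`ExpressionMatrix`.

    Expects ``matrix.mtx``, ``barcodes.tsv`` and ``features.tsv`` (or
    ``genes.tsv``), plain or gzipped, with genes as matrix rows. The gene
    symbol is taken from the second column of the features file when
    present (10x convention: id, symbol, type), otherwise the first.
    Duplicate symbols are disambiguated deterministically with ``.N``
    suffixes in file order.
    """
    dir_path = Path(dir_path)
    if not dir_path.is_dir():
        raise InputError(f"not a directory: {dir_path}")
    mtx_path = _find_sidecar(dir_path, "matrix.mtx")
    barcodes_path = _find_sidecar(dir_path, "barcodes.tsv")
    try:
        features_path = _find_sidecar(dir_path, "features.tsv")
    except InputError:
        features_path = _find_sidecar(dir_path, "genes.tsv")

    try:
        with _open_text(mtx_path) as fh:
            mat = scipy.io.mmread(fh)
    except Exception as exc:
        raise FormatError(f"cannot parse {mtx_path} as MatrixMarket: {exc}") from exc
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    values = np.asarray(mat, dtype=float)

    barcodes = [line.split("\t")[0] for line in _read_lines(barcodes_path)]
    feature_rows = [line.split("\t") for line in _read_lines(features_path)]
    symbols = [row[1] if len(row) > 1 else row[0] for row in feature_rows]

    if values.shape[0] != len(symbols):
        raise FormatError(
            f"{mtx_path.name} declares {values.shape[0]} genes but "
            f"{features_path.name} has {len(symbols)} lines"
        )
    if values.shape[1] != len(barcodes):
        raise FormatError(
            f"{mtx_path.name} declares {values.shape[1]} cells but "
            f"{barcodes_path.name} has {len(barcodes)} lines"
        )
    return ExpressionMatrix(np.array(deduplicate_ids(symbols), dtype=object),
                            np.array(barcodes, dtype=object), values)


def write_10x_mtx(expr: ExpressionMatrix, dir_path: str | Path) -> None:
    """Write a MatrixMarket triplet directory (matrix.mtx, barcodes.tsv, features.tsv)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(expr.values)
    scipy.io.mmwrite(dir_path / "matrix.mtx", sparse, precision=12)
    with open(dir_path / "barcodes.tsv", "w") as fh:
        fh.writelines(f"{c}\n" for c in expr.cell_ids)
    with open(dir_path / "features.tsv", "w") as fh:
        fh.writelines(f"{g}\t{g}\tGene Expression\n" for g in expr.gene_ids)


def read_dense_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a dense genes x cells TSV (header: cell ids; first column: gene ids)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing file {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as TSV: {exc}") from exc
    if df.shape[0] == 0:
        warnings.warn(f"{path}: no gene rows (header only)", stacklevel=2)
    genes = [str(g) for g in df.index]
    dup_mask = pd.Index(genes).duplicated(keep=False)
    dups = sorted(set(np.array(genes, dtype=object)[dup_mask]))
    if dups:
        raise FormatError(f"{path}: duplicate gene ids: {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression value: {exc}") from exc
    if values.size and np.min(values) < 0:
        raise InputError(f"{path}: negative expression values are not supported")
    return ExpressionMatrix(np.array(genes, dtype=object),
                            np.array([str(c) for c in df.columns], dtype=object), values)


def write_dense_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", float_format="%.12g")


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Dispatch to the MatrixMarket-directory or dense-TSV reader by path type."""
    path = Path(path)
    return read_10x_mtx(path) if path.is_dir() else read_dense_tsv(path)


def read_clusters(path: str | Path) -> ClusterAssignment:
    """Read a two-column TSV of (cell_id, cluster_label), optional header.

    A first row whose fields match conventional column names
    (cell/barcode, cluster/label) is treated as a header. Cluster labels
    are opaque strings ordered by first appearance.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing file {path}")
    rows = []
    for lineno, line in enumerate(_read_lines(path), start=1):
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}")
        rows.append((parts[0].strip(), parts[1].strip()))
    if not rows:
        raise InputError(f"{path}: empty cluster table")
    if rows[0][0].lower() in _CELL_HEADERS and rows[0][1].lower() in _CLUSTER_HEADERS:
        rows = rows[1:]
    mapping: dict[str, str] = {}
    for cell, label in rows:
        if cell in mapping and mapping[cell] != label:
            raise InputError(
                f"{path}: cell {cell!r} assigned to both {mapping[cell]!r} and {label!r}"
            )
        mapping.setdefault(cell, label)
    order: list[str] = []
    for _, label in rows:
        if label not in order:
            order.append(label)
    return ClusterAssignment(mapping, order)


def write_clusters(clusters: ClusterAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cell, label in clusters.cell_to_cluster.items():
            fh.write(f"{cell}\t{label}\n")


def read_markers(path: str | Path, format: str | None = None) -> MarkerCatalog:
    """Read a marker catalog from two-column CSV or GMT.

    CSV rows are ``cell_type,gene`` pairs (optional header); GMT lines are
    ``set_name<TAB>description<TAB>member...``. The within-type marker
    order of the file is preserved. The format is inferred from the
    extension when not given.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"missing file {path}")
    if format is None:
        format = "gmt" if path.suffix.lower() == ".gmt" else "csv"
    if format not in ("csv", "gmt"):
        raise InputError(f"unknown marker format {format!r} (expected 'csv' or 'gmt')")

    entries: dict[str, list[str]] = {}
    if format == "gmt":
        for lineno, line in enumerate(_read_lines(path), start=1):
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs set name, description and >=1 member"
                )
            name, members = parts[0], [m for m in parts[2:] if m]
            if name in entries:
                raise InputError(f"{path}: duplicate gene set {name!r}")
            entries[name] = members
    else:
        with _open_text(path) as fh:
            reader = csv.reader(fh)
            rows = [row for row in reader if row and any(f.strip() for f in row)]
        if not rows:
            raise InputError(f"{path}: empty marker file")
        if len(rows[0]) < 2:
            raise FormatError(f"{path}: CSV needs two columns (cell_type,gene)")
        if rows[0][0].strip().lower() in _TYPE_HEADERS and rows[0][1].strip().lower() in _GENE_HEADERS:
            rows = rows[1:]
        for lineno, row in enumerate(rows, start=1):
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise FormatError(f"{path}: row {lineno}: expected (cell_type,gene) pair")
            entries.setdefault(row[0].strip(), []).append(row[1].strip())
    return MarkerCatalog(entries)


def write_markers_csv(catalog: MarkerCatalog, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_type", "gene"])
        for cell_type, markers in catalog.entries.items():
            for m in markers:
                writer.writerow([cell_type, m])


def write_cta_matrix(m: "CTAMatrix", path: str | Path) -> None:
    """Write a CTA matrix as TSV: cell types as rows, cluster labels as columns.

    Values are written with 12 significant digits, enough for a
    bit-faithful round-trip through :func:`read_cta_matrix` at 1e-12.
    """
    df = pd.DataFrame(m.scores, index=m.cell_types, columns=m.cluster_labels)
    df.index.name = "cell_type"
    try:
        df.to_csv(path, sep="\t", float_format="%.12g")
    except OSError as exc:
        raise InputError(f"cannot write {path}: {exc}") from exc


def read_cta_matrix(path: str | Path) -> "CTAMatrix":
    from .core import CTAMatrix

    path = Path(path)
    if not path.exists():
        raise InputError(f"missing file {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CTAMatrix(
        cell_types=[str(x) for x in df.index],
        cluster_labels=[str(x) for x in df.columns],
        scores=df.to_numpy(dtype=float),
    )
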