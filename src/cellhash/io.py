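"""Reading and writing digital gene expression (DGE) matrices.

A DGE matrix holds UMI counts with genes as rows and cells as columns.
Supported on-disk formats are MatrixMarket coordinate files with
``genes.tsv``/``features.tsv`` and ``barcodes.tsv`` sidecars, and delimited
text (CSV/TSV) with a gene-name index column and a cell-name header row.
Gzip-compressed variants of all of these are accepted.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "AlignmentReport",
    "read_dge",
    "write_dge",
    "align_genes",
]


@dataclass
class AlignmentReport:
    """Summary of a gene alignment between a query and a reference gene set."""

    n_shared: int
    n_dropped: int  # query genes absent from the reference
    n_filled: int  # reference genes absent from the query (zero-filled)
    dropped_genes: list[str] = field(default_factory=list)
    filled_genes: list[str] = field(default_factory=list)


@dataclass
class ExpressionMatrix:
    """Named genes x cells UMI count matrix.

    Parameters
    ----------
    counts
        Non-negative integer matrix of shape (n_genes, n_cells); dense
        ndarray or any scipy sparse matrix.
    gene_names
        Unique gene names, one per row.
    cell_names
        Unique cell names, one per column.
    """

    counts: np.ndarray | sp.spmatrix
    gene_names: list[str]
    cell_names: list[str]
    alignment_report: Optional[AlignmentReport] = None

    def __post_init__(self) -> None:
        self.gene_names = [str(g).strip() for g in self.gene_names]
        self.cell_names = [str(c).strip() for c in self.cell_names]
        m, n = self.counts.shape
        if m != len(self.gene_names):
            raise ValueError(
                f"counts has {m} rows but {len(self.gene_names)} gene names"
            )
        if n != len(self.cell_names):
            raise ValueError(
                f"counts has {n} columns but {len(self.cell_names)} cell names"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            seen: set[str] = set()
            for g in self.gene_names:
                if g in seen:
                    raise ValueError(f"duplicate gene name: {g!r}")
                seen.add(g)
        if len(set(self.cell_names)) != len(self.cell_names):
            raise ValueError("cell names are not unique")
        _check_counts(self.counts)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        """Counts as a dense int64 ndarray."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=np.int64)
        return np.asarray(self.counts, dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.gene_names, columns=self.cell_names)


def _check_counts(counts: np.ndarray | sp.spmatrix) -> None:
    data = counts.data if sp.issparse(counts) else np.asarray(counts)
    if data.size == 0:
        return
    if np.issubdtype(data.dtype, np.floating):
        frac = data != np.floor(data)
        if sp.issparse(counts):
            if frac.any():
                i = int(np.flatnonzero(frac)[0])
                raise ValueError(
                    f"non-integer count {counts.data[i]!r} in sparse entry {i}"
                )
        elif frac.any():
            r, c = np.argwhere(frac)[0]
            raise ValueError(f"non-integer count at row {r}, column {c}: {data[r, c]!r}")
    if data.min() < 0:
        raise ValueError("counts contain negative entries")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_names(path: Path) -> list[str]:
    names = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            # 10x-style features files carry id/symbol/type columns; take the
            # first field as the identifier.
            names.append(line.split("\t")[0].strip())
    return names


def _find_sidecar(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            cand = directory / (stem + suffix)
            if cand.exists():
                return cand
    raise FileNotFoundError(
        f"no sidecar file matching {list(stems)} found in {directory}"
    )


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".gz"):
        name = name[: -len(".gz")]
    if name.endswith(".mtx"):
        return "mtx"
    if name.endswith(".csv"):
        return "csv"
    if name.endswith(".tsv") or name.endswith(".txt"):
        return "tsv"
    raise ValueError(f"cannot infer format from file name {path.name!r}")


def read_dge(path: str | Path, format: str = "auto") -> ExpressionMatrix:
    """Read a DGE matrix from disk.

    For MatrixMarket input, gene and cell names are taken from
    ``genes.tsv``/``features.tsv`` and ``barcodes.tsv`` files in the same
    directory; orientation on disk is resolved by matching sidecar lengths
    against the matrix dimensions, and the returned matrix is always
    gene-major (genes x cells).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "auto":
        format = _detect_format(path)
    if format == "mtx":
        return _read_mtx(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        return ExpressionMatrix(
            counts=_as_int_counts(df.to_numpy()),
            gene_names=[str(g) for g in df.index],
            cell_names=[str(c) for c in df.columns],
        )
    raise ValueError(f"unknown format {format!r}")


def _as_int_counts(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.floating):
        frac = arr != np.floor(arr)
        if frac.any():
            r, c = np.argwhere(frac)[0]
            raise ValueError(
                f"non-integer count at row {r}, column {c}: {arr[r, c]!r}"
            )
        arr = arr.astype(np.int64)
    return arr


def _read_mtx(path: Path) -> ExpressionMatrix:
    mat = scipy.io.mmread(str(path)).tocsc()
    _check_counts(mat)
    mat = mat.astype(np.int64)
    directory = path.parent
    genes = _read_names(_find_sidecar(directory, ["genes.tsv", "features.tsv"]))
    cells = _read_names(_find_sidecar(directory, ["barcodes.tsv"]))
    m, n = mat.shape
    if m == len(genes) and n == len(cells):
        if m == n and len(genes) == len(cells):
            raise ValueError(
                "ambiguous orientation: square matrix with equal-length sidecars"
            )
        pass
    elif m == len(cells) and n == len(genes):
        mat = mat.T.tocsc()
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither "
            f"(genes={len(genes)}, cells={len(cells)}) orientation"
        )
    return ExpressionMatrix(counts=mat, gene_names=genes, cell_names=cells)


def write_dge(X: ExpressionMatrix, path: str | Path, format: str = "auto") -> None:
    """Write a DGE matrix; the inverse of :func:`read_dge` on counts and names."""
    path = Path(path)
    if format == "auto":
        format = _detect_format(path)
    if format == "mtx":
        mat = sp.coo_matrix(X.counts)
        scipy.io.mmwrite(str(path), mat, field="integer")
        directory = path.parent
        (directory / "genes.tsv").write_text("".join(g + "\n" for g in X.gene_names))
        (directory / "barcodes.tsv").write_text("".join(c + "\n" for c in X.cell_names))
    elif format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        X.to_frame().to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown format {format!r}")


def align_genes(query: ExpressionMatrix, reference_genes: Sequence[str]) -> ExpressionMatrix:
    """Reindex a query matrix onto a reference gene list.

    Output rows follow ``reference_genes`` exactly: shared genes keep their
    query counts, reference genes missing from the query become zero rows,
    and query genes not in the reference are dropped.  An
    :class:`AlignmentReport` is attached to the result.
    """
    reference_genes = [str(g).strip() for g in reference_genes]
    if len(set(reference_genes)) != len(reference_genes):
        raise ValueError("reference gene names are not unique")
    qpos = {g: i for i, g in enumerate(query.gene_names)}
    shared = [g for g in reference_genes if g in qpos]
    if not shared:
        raise ValueError("query and reference share no gene names")
    dropped = sorted(set(query.gene_names) - set(reference_genes))
    filled = [g for g in reference_genes if g not in qpos]

    n = query.n_cells
    ref_rows = np.array([i for i, g in enumerate(reference_genes) if g in qpos])
    src_rows = np.array([qpos[g] for g in shared])
    sub = sp.csr_matrix(query.counts)[src_rows].tocoo()
    out = sp.coo_matrix(
        (sub.data, (ref_rows[sub.row], sub.col)),
        shape=(len(reference_genes), n),
        dtype=np.int64,
    ).tocsr()
    result = ExpressionMatrix(
        counts=out.tocsr(),
        gene_names=reference_genes,
        cell_names=list(query.cell_names),
    )
    result.alignment_report = AlignmentReport(
        n_shared=len(shared),
        n_dropped=len(dropped),
        n_filled=len(filled),
        dropped_genes=dropped,
        filled_genes=filled,
    )
    return result
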