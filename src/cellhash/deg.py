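"""Single-cell differential expression against a matched neighborhood.

A query cell u matched to database cell v is compared against the k-nearest
neighborhood of v (v included).  Each neighbor's raw UMI counts are scaled
to the query's library size and averaged; under the assumption that the
neighborhood is biologically homogeneous and that UMI counts are Poisson
with rates proportional to capture efficiency, this mean is an unbiased
estimator of the query's expected count per gene.  Genes whose observed
count is improbably small (lower tail) or large (upper tail) under
Poisson(lambda_i) are flagged as candidate DEGs.  Tail probabilities are
raw, uncorrected for multiple testing; the default threshold is 1e-4.

Raw counts live in a per-cell compressed store (zlib), decompressed only on
request, so DEG support costs disk space but little memory.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.stats

from .hashing import hamming_distance
from .io import ExpressionMatrix, align_genes
from .mih import knn_search

__all__ = [
    "CompressedCounts",
    "DEGResult",
    "neighborhood_mean",
    "poisson_tails",
    "detect_degs",
]


@dataclass
class CompressedCounts:
    """Raw gene x cell counts, one zlib-compressed block per cell.

    Each block packs the cell's nonzero (gene index, count) pairs; columns
    decompress independently, so reading one cell never touches the rest.
    """

    gene_names: list[str]
    cell_names: list[str]
    blocks: list[bytes]
    totals: np.ndarray  # per-cell total counts

    @classmethod
    def from_matrix(cls, X: ExpressionMatrix) -> "CompressedCounts":
        import scipy.sparse as sp

        csc = sp.csc_matrix(X.counts)
        blocks = []
        totals = np.zeros(X.n_cells, dtype=np.int64)
        for j in range(X.n_cells):
            col = csc[:, j].tocoo()
            idx = col.row.astype(np.uint32)
            val = col.data.astype(np.uint32)
            payload = idx.tobytes() + val.tobytes()
            blocks.append(zlib.compress(payload, level=9))
            totals[j] = int(val.sum())
        return cls(
            gene_names=list(X.gene_names),
            cell_names=list(X.cell_names),
            blocks=blocks,
            totals=totals,
        )

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    @property
    def n_cells(self) -> int:
        return len(self.blocks)

    def cell_counts(self, j: int) -> np.ndarray:
        """Decompress cell j into a dense int64 vector over all genes."""
        payload = zlib.decompress(self.blocks[j])
        half = len(payload) // 2
        idx = np.frombuffer(payload[:half], dtype=np.uint32)
        val = np.frombuffer(payload[half:], dtype=np.uint32)
        out = np.zeros(self.n_genes, dtype=np.int64)
        out[idx.astype(np.int64)] = val
        return out


@dataclass
class DEGResult:
    """Per-gene DEG evidence for one query cell."""

    gene_names: list[str]
    query_counts: np.ndarray  # y_i
    neighborhood_means: np.ndarray  # lambda_i
    tail_lower: np.ndarray  # P(Y <= y_i)
    tail_upper: np.ndarray  # P(Y >= y_i)
    negative: np.ndarray  # bool flags, lower tail < alpha
    positive: np.ndarray  # bool flags, upper tail < alpha
    alpha: float
    neighborhood: list[int]  # database positions of the k neighbors

    def flagged_genes(self) -> list[tuple[str, str]]:
        out = []
        for g, neg, pos in zip(self.gene_names, self.negative, self.positive):
            if neg:
                out.append((g, "negative"))
            if pos:
                out.append((g, "positive"))
        return out


def _require_raw_store(db) -> CompressedCounts:
    store = getattr(db, "raw_store_", None)
    if store is None:
        raise ValueError(
            "database stores no raw counts; rebuild with store_counts=True "
            "(CLI: --store-counts) to enable DEG detection"
        )
    return store


def _db_knn_of_member(db, position: int, k: int) -> list[int]:
    """k-NN of a database cell among database cells, by total Hamming distance.

    Uses the cell's stored hash codes directly (no re-preprocessing); the
    cell itself is at distance 0 and is part of its own neighborhood.
    """
    cand: set[int] = set()
    qcodes = [mih.codes.words[position] for _, mih in db.hashes_]
    for qw, (_, mih) in zip(qcodes, db.hashes_):
        cand.update(p for p, _ in knn_search(mih, qw, k))
    positions = np.fromiter(cand, dtype=np.int64)
    total = np.zeros(positions.shape[0], dtype=np.int64)
    for qw, (_, mih) in zip(qcodes, db.hashes_):
        total += hamming_distance(qw, mih.codes.words[positions])
    order = np.lexsort((positions, total))
    return [int(positions[i]) for i in order[: min(k, positions.size)]]


def neighborhood_mean(
    db, v: int | str, k: int = 10, n_u: Optional[float] = None
) -> tuple[np.ndarray, list[int]]:
    """Mean of the k neighbors' counts, each scaled to library size ``n_u``.

    ``v`` is a database cell (position or name); its k nearest database
    cells (v included) are retrieved in the hashed space, each neighbor's
    raw counts are multiplied by ``n_u / (neighbor total)``, and the
    per-gene arithmetic mean is returned together with the neighbor
    positions.
    """
    store = _require_raw_store(db)
    if isinstance(v, str):
        v = db.cell_names_.index(v)
    if k < 1:
        raise ValueError("k must be at least 1")
    neighbors = _db_knn_of_member(db, int(v), k)
    if n_u is None:
        n_u = float(store.totals[v])
    lam = np.zeros(store.n_genes, dtype=np.float64)
    for j in neighbors:
        total_j = float(store.totals[j])
        if total_j <= 0:
            raise ValueError(f"database cell {j} has zero total count")
        lam += store.cell_counts(j) * (n_u / total_j)
    lam /= len(neighbors)
    return lam, neighbors


def poisson_tails(
    y: np.ndarray | int, lam: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Poisson tails (P(Y <= y), P(Y >= y)); both include the mass at y.

    Computed via the regularized incomplete gamma function (scipy), which is
    stable for large means; lambda = 0 degenerates to a point mass at 0.
    """
    y_arr = np.asarray(y)
    lam_arr = np.asarray(lam, dtype=np.float64)
    if np.any(y_arr < 0) or np.any(lam_arr < 0):
        raise ValueError("counts and means must be non-negative")
    if not np.issubdtype(y_arr.dtype, np.integer):
        if np.any(y_arr != np.floor(y_arr)):
            raise ValueError("counts must be integers")
        y_arr = y_arr.astype(np.int64)
    lower = scipy.stats.poisson.cdf(y_arr, lam_arr)
    upper = scipy.stats.poisson.sf(y_arr - 1, lam_arr)
    if np.isscalar(y) and np.isscalar(lam):
        return float(lower), float(upper)
    return lower, upper


def detect_degs(
    db,
    query_counts: ExpressionMatrix | np.ndarray,
    matched_cell: int | str,
    k: int = 10,
    alpha: float = 1e-4,
    gene_names: Optional[Sequence[str]] = None,
) -> DEGResult:
    """Flag genes of a query cell that deviate from its matched neighborhood.

    ``query_counts`` is a single cell: an :class:`ExpressionMatrix` with one
    column, or a count vector with ``gene_names``.  Genes with
    P(Y <= y) < alpha are flagged negative (down in the query), genes with
    P(Y >= y) < alpha positive.
    """
    store = _require_raw_store(db)
    if not isinstance(query_counts, ExpressionMatrix):
        vec = np.asarray(query_counts).reshape(-1)
        if gene_names is None:
            raise ValueError("gene_names are required with a bare count vector")
        query_counts = ExpressionMatrix(
            vec[:, None], list(gene_names), ["query"]
        )
    if query_counts.n_cells != 1:
        raise ValueError("detect_degs expects a single query cell")
    aligned = align_genes(query_counts, store.gene_names)
    y = aligned.dense()[:, 0]
    n_u = float(y.sum())
    if n_u <= 0:
        raise ValueError("query cell has zero total count")
    lam, neighbors = neighborhood_mean(db, matched_cell, k=k, n_u=n_u)
    lower, upper = poisson_tails(y, lam)
    # A neighborhood with zero observed counts gives the degenerate point
    # estimate lambda = 0, under which any nonzero query count has tail
    # probability exactly 0 regardless of how weakly the gene is expressed.
    # For flagging (reported tails stay exact), such genes are instead
    # tested against the largest mean still consistent with an all-zero
    # neighborhood: the exact one-sided Poisson upper confidence bound
    # ln(1/alpha) / sum_j(n_vj / n_u) on the query count scale.
    exposure = float(np.sum(store.totals[neighbors]) / n_u)
    lam_floor = np.log(1.0 / alpha) / exposure
    lam_flag = np.where(lam > 0, lam, lam_floor)
    flag_lower, flag_upper = poisson_tails(y, lam_flag)
    return DEGResult(
        gene_names=list(store.gene_names),
        query_counts=y,
        neighborhood_means=lam,
        tail_lower=lower,
        tail_upper=upper,
        negative=flag_lower < alpha,
        positive=flag_upper < alpha,
        alpha=alpha,
        neighborhood=neighbors,
    )
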