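"""Cell search databases: build (preprocess, hash, index) and query.

A database holds the fitted preprocessor, L independent signed-random-
projection hashes with their multi-index Hamming structures, per-cell
metadata, and optionally the compressed raw counts needed for DEG
detection.  A query cell is folded into the reference reduced space,
hashed by each of the L hyperplane sets, and each index returns its k
nearest candidates; the union of the <= kL candidates is re-scored by the
*total* Hamming distance over all L codes (T*L bits), from which a cosine
similarity is estimated.  More, and longer, hashes trade computation for a
lower-variance similarity estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.metrics import cohen_kappa_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .hashing import (
    BitCodes,
    HyperplaneSet,
    cosine_from_hamming,
    encode,
    generate_hyperplanes,
    hamming_distance,
)
from .io import ExpressionMatrix
from .mih import MultiIndexHash, build_mih, knn_search
from .preprocessing import CellPreprocessor

__all__ = [
    "CellDatabase",
    "SearchResult",
    "build_database",
    "query",
    "consistency_score",
    "cohens_kappa",
    "fivefold_self_mapping",
]

FORMAT_VERSION = 1
_VALID_BITS = (64, 128, 256, 512)


@dataclass
class SearchResult:
    """k nearest database cells for each query cell.

    All arrays have shape (n_queries, k).  ``distances`` are total Hamming
    distances out of ``n_bits_total`` = T*L; ``similarities`` are the
    cosine-similarity estimates derived from them.  Within each query row
    the distances are non-decreasing, ties broken by database position.
    """

    positions: np.ndarray
    distances: np.ndarray
    similarities: np.ndarray
    neighbor_names: np.ndarray
    query_names: list[str]
    n_bits_total: int

    @property
    def k(self) -> int:
        return self.positions.shape[1]


class CellDatabase(BaseEstimator):
    """Searchable database of hashed single-cell expression profiles.

    Scikit-learn style estimator: ``fit`` builds the database from reference
    cells (an :class:`ExpressionMatrix` or a (n_cells, n_genes) array) with
    optional labels ``y``; ``kneighbors`` returns the k nearest database
    cells per query; ``predict`` transfers the nearest neighbor's label.

    Parameters
    ----------
    n_bits : bits per hash code T (64, 128, 256 or 512; default 128).
    n_hashes : number L of independent hash indexes (default 4).
    n_dims : dimensionality D of the reduced space (default 50).
    count_transform : "log1p" or "ftt" variance-stabilizing transform.
    min_features_fraction : feature-selection floor (default 0.10).
    scale_factor : common library size after normalization.
    store_counts : keep a compressed copy of the raw counts (enables DEG
        detection).
    subcode_bits : multi-index block width; default ~log2(N) clamped to
        [8, 16].
    random_state : master seed; hash index l uses seed ``random_state + l``.
    """

    def __init__(
        self,
        n_bits: int = 128,
        n_hashes: int = 4,
        n_dims: int = 50,
        count_transform: str = "log1p",
        min_features_fraction: float = 0.10,
        keep_genes: Optional[Sequence[str]] = None,
        drop_genes: Optional[Sequence[str]] = None,
        scale_factor: float = 1e4,
        store_counts: bool = False,
        subcode_bits: Optional[int] = None,
        random_state: int = 0,
    ):
        self.n_bits = n_bits
        self.n_hashes = n_hashes
        self.n_dims = n_dims
        self.count_transform = count_transform
        self.min_features_fraction = min_features_fraction
        self.keep_genes = keep_genes
        self.drop_genes = drop_genes
        self.scale_factor = scale_factor
        self.store_counts = store_counts
        self.subcode_bits = subcode_bits
        self.random_state = random_state

    # -- building ---------------------------------------------------------

    def fit(self, X, y=None, gene_names=None, cell_names=None):
        if self.n_bits not in _VALID_BITS:
            raise ValueError(f"n_bits must be one of {_VALID_BITS}")
        if self.n_hashes < 1:
            raise ValueError("n_hashes must be at least 1")
        seed = int(self.random_state) % (2**31)

        prep = CellPreprocessor(
            min_features_fraction=self.min_features_fraction,
            count_transform=self.count_transform,
            n_dims=self.n_dims,
            keep_genes=self.keep_genes,
            drop_genes=self.drop_genes,
            scale_factor=self.scale_factor,
            random_state=seed,
        )
        X = prep._coerce(X, gene_names)
        if cell_names is not None:
            X = ExpressionMatrix(X.counts, X.gene_names, list(cell_names))
        reduced = prep.fit_transform(X)

        hashes: list[tuple[HyperplaneSet, MultiIndexHash]] = []
        for l in range(self.n_hashes):
            H = generate_hyperplanes(
                D=self.n_dims,
                T=self.n_bits,
                orthogonalize=True,
                rng_seed=(seed + l) % (2**31),
            )
            codes = encode(reduced, H)
            hashes.append((H, build_mih(codes, self.subcode_bits)))

        self.preprocessor_ = prep
        self.hashes_ = hashes
        self.cell_names_ = list(X.cell_names)
        self.labels_ = None if y is None else np.asarray(y)
        if self.labels_ is not None and len(self.labels_) != X.n_cells:
            raise ValueError("labels length does not match the number of cells")
        self.build_seed_ = seed
        self.format_version_ = FORMAT_VERSION
        if self.store_counts:
            from .deg import CompressedCounts

            self.raw_store_ = CompressedCounts.from_matrix(X)
        else:
            self.raw_store_ = None
        return self

    @property
    def n_cells_(self) -> int:
        check_is_fitted(self, "hashes_")
        return self.hashes_[0][1].n_codes

    # -- querying ---------------------------------------------------------

    def _encode_query(self, Q, gene_names=None, query_stats: bool = False) -> list[BitCodes]:
        reduced = self.preprocessor_.transform(
            Q, gene_names=gene_names, query_stats=query_stats
        )
        return [encode(reduced, H) for H, _ in self.hashes_]

    def _rank_candidates(
        self, qcodes: list[np.ndarray], candidates: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Total Hamming distance over all L codes for the given positions."""
        total = np.zeros(candidates.shape[0], dtype=np.int64)
        for qw, (_, mih) in zip(qcodes, self.hashes_):
            total += hamming_distance(qw, mih.codes.words[candidates])
        order = np.lexsort((candidates, total))
        return candidates[order], total[order]

    def kneighbors(
        self, Q, k: int = 10, gene_names=None, query_stats: bool = False
    ) -> SearchResult:
        """k nearest database cells per query cell by total Hamming distance."""
        check_is_fitted(self, "hashes_")
        if k < 1:
            raise ValueError("k must be at least 1")
        Qm = self.preprocessor_._coerce(Q, gene_names)
        codes_per_index = self._encode_query(Qm, query_stats=query_stats)
        n_query = Qm.n_cells
        k_eff = min(k, self.n_cells_)
        positions = np.empty((n_query, k_eff), dtype=np.int64)
        distances = np.empty((n_query, k_eff), dtype=np.int64)
        for j in range(n_query):
            qcodes = [c.words[j] for c in codes_per_index]
            cand: set[int] = set()
            for qw, (_, mih) in zip(qcodes, self.hashes_):
                cand.update(p for p, _ in knn_search(mih, qw, k_eff))
            ranked_pos, ranked_dist = self._rank_candidates(
                qcodes, np.fromiter(cand, dtype=np.int64)
            )
            positions[j] = ranked_pos[:k_eff]
            distances[j] = ranked_dist[:k_eff]
        total_bits = self.n_bits * self.n_hashes
        names = np.asarray(self.cell_names_, dtype=object)[positions]
        return SearchResult(
            positions=positions,
            distances=distances,
            similarities=cosine_from_hamming(distances, total_bits),
            neighbor_names=names,
            query_names=list(Qm.cell_names),
            n_bits_total=total_bits,
        )

    def predict(self, Q, gene_names=None, query_stats: bool = False) -> np.ndarray:
        """Label of each query's nearest database cell."""
        check_is_fitted(self, "hashes_")
        if self.labels_ is None:
            raise ValueError("database was built without labels")
        res = self.kneighbors(Q, k=1, gene_names=gene_names, query_stats=query_stats)
        return self.labels_[res.positions[:, 0]]


def build_database(
    X: ExpressionMatrix,
    labels: Optional[Sequence] = None,
    n_bits: int = 128,
    n_hashes: int = 4,
    n_dims: int = 50,
    seed: int = 0,
    **kwargs,
) -> CellDatabase:
    """Build a :class:`CellDatabase` from reference cells (thin wrapper)."""
    db = CellDatabase(
        n_bits=n_bits, n_hashes=n_hashes, n_dims=n_dims, random_state=seed, **kwargs
    )
    return db.fit(X, y=labels)


def query(db: CellDatabase, Q: ExpressionMatrix, k: int = 10, **kwargs) -> SearchResult:
    """Query a database for the k nearest cells (thin wrapper)."""
    return db.kneighbors(Q, k=k, **kwargs)


def consistency_score(true_labels: Sequence, predicted_labels: Sequence) -> float:
    """Fraction of positions with equal labels (1 = perfect agreement)."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    return float(np.mean(t == p))


def cohens_kappa(true_labels: Sequence, predicted_labels: Sequence) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e)."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    if len(set(t) | set(p)) == 1:
        # single shared label: expected agreement is 1, kappa defined only
        # for perfect observed agreement
        if np.all(t == p):
            return 1.0
        raise ValueError("kappa undefined: expected agreement is 1")
    return float(cohen_kappa_score(t, p))


def fivefold_self_mapping(
    X: ExpressionMatrix,
    labels: Sequence,
    n_folds: int = 5,
    k: int = 10,
    seed: int = 0,
    query_stats: bool = False,
    **db_params,
) -> list[dict]:
    """Stratified n-fold self-mapping: map each fold onto the rest.

    Each fold's cells are queried against a database built from the other
    folds; the nearest neighbor's label is transferred and scored.  Returns
    one dict per fold with consistency and kappa.
    """
    labels = np.asarray(labels)
    counts = X.dense()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    results = []
    for fold, (train, test) in enumerate(skf.split(labels, labels)):
        ref = ExpressionMatrix(
            counts[:, train],
            X.gene_names,
            [X.cell_names[i] for i in train],
        )
        qry = ExpressionMatrix(
            counts[:, test],
            X.gene_names,
            [X.cell_names[i] for i in test],
        )
        db = CellDatabase(random_state=seed + fold, **db_params)
        db.fit(ref, y=labels[train])
        # k neighbors are retrieved but only the nearest transfers its label
        res = db.kneighbors(qry, k=k, query_stats=query_stats)
        predicted = db.labels_[res.positions[:, 0]]
        results.append(
            {
                "fold": fold,
                "consistency": consistency_score(labels[test], predicted),
                "kappa": cohens_kappa(labels[test], predicted),
                "n_query": len(test),
            }
        )
    return results
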