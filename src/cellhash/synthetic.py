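"""Clustered scRNA-seq-like UMI count generator with known ground truth.

Emulates the structure the search method assumes: discrete cell-type
clusters whose mean expression vectors differ only at disjoint sets of
marker genes, per-cell library sizes, optional multiplicative per-batch
gene-wise scaling (a simple batch effect), and Poisson (or negative
binomial) sampling noise.  Every dataset carries its ground truth — cluster
labels, marker sets, batch assignments — so label transfer and DEG
detection can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "SynthSpec",
    "SynthTruth",
    "make_dataset",
    "make_deg_pair",
    "choose_spike_genes",
]


@dataclass
class SynthSpec:
    """Parameters of the generator.

    Defaults produce five well-separated cell types (100 marker genes each,
    4-fold up-regulated) over 2000 genes and 500 cells, with UMI library
    sizes uniform in [1000, 5000] and Poisson noise — a small but realistic
    droplet-style dataset.
    """

    n_genes: int = 2000
    n_cells: int = 500
    n_clusters: int = 5
    marker_genes_per_cluster: int = 100
    log2_fold_change: float = 2.0
    library_size_range: tuple[int, int] = (1000, 5000)
    n_batches: int = 1
    batch_scaling_sd: float = 0.0
    noise: str = "poisson"  # or "nb"
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters * self.marker_genes_per_cluster > self.n_genes:
            raise ValueError(
                "marker_genes_per_cluster * n_clusters exceeds n_genes"
            )
        if self.noise not in ("poisson", "nb"):
            raise ValueError("noise must be 'poisson' or 'nb'")
        if self.n_batches < 1:
            raise ValueError("n_batches must be at least 1")


@dataclass
class SynthTruth:
    """Ground truth attached to a generated dataset."""

    labels: np.ndarray  # cluster label per cell, strings
    batches: np.ndarray  # batch index per cell
    marker_genes: dict[str, list[str]]  # cluster -> marker gene names
    gene_means: np.ndarray  # base relative expression per gene
    library_sizes: np.ndarray


def _sample_counts(rng: np.random.Generator, mean: np.ndarray, spec: SynthSpec) -> np.ndarray:
    if spec.noise == "poisson":
        return rng.poisson(mean)
    # NB via gamma-Poisson: var = mu + dispersion * mu^2
    shape = 1.0 / spec.nb_dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def make_dataset(spec: SynthSpec) -> tuple[ExpressionMatrix, np.ndarray, SynthTruth]:
    """Generate a clustered count matrix; returns (matrix, labels, truth)."""
    rng = np.random.default_rng(spec.seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)

    # disjoint marker blocks, one per cluster
    marker_idx = rng.permutation(spec.n_genes)[
        : spec.n_clusters * spec.marker_genes_per_cluster
    ].reshape(spec.n_clusters, spec.marker_genes_per_cluster)
    cluster_means = np.tile(base, (spec.n_clusters, 1))
    fold = 2.0**spec.log2_fold_change
    for c in range(spec.n_clusters):
        cluster_means[c, marker_idx[c]] *= fold

    labels_int = rng.integers(0, spec.n_clusters, size=spec.n_cells)
    batches = np.arange(spec.n_cells) % spec.n_batches
    lib_lo, lib_hi = spec.library_size_range
    lib_sizes = rng.integers(lib_lo, lib_hi + 1, size=spec.n_cells)

    if spec.batch_scaling_sd > 0:
        batch_factors = rng.lognormal(
            mean=0.0, sigma=spec.batch_scaling_sd, size=(spec.n_batches, spec.n_genes)
        )
    else:
        batch_factors = np.ones((spec.n_batches, spec.n_genes))

    counts = np.empty((spec.n_genes, spec.n_cells), dtype=np.int64)
    for j in range(spec.n_cells):
        mu = cluster_means[labels_int[j]] * batch_factors[batches[j]]
        mu = mu / mu.sum() * lib_sizes[j]
        counts[:, j] = _sample_counts(rng, mu, spec)

    gene_names = [f"gene{i}" for i in range(spec.n_genes)]
    cell_names = [f"cell{j}" for j in range(spec.n_cells)]
    labels = np.array([f"type{c}" for c in labels_int])
    matrix = ExpressionMatrix(counts=counts, gene_names=gene_names, cell_names=cell_names)
    truth = SynthTruth(
        labels=labels,
        batches=batches,
        marker_genes={
            f"type{c}": [gene_names[i] for i in marker_idx[c]]
            for c in range(spec.n_clusters)
        },
        gene_means=base,
        library_sizes=lib_sizes,
    )
    return matrix, labels, truth


def choose_spike_genes(
    spec: SynthSpec,
    n: int = 10,
    expected_count_range: tuple[float, float] = (8.0, 30.0),
) -> list[str]:
    """Pick genes to spike in a DEG experiment, by expected count.

    Reproduces the base expression profile that :func:`make_deg_pair` will
    draw for ``spec`` and selects ``n`` genes whose expected UMI count at
    the median library size falls inside ``expected_count_range``.  The
    band keeps spiked genes well expressed (so the Poisson test has power)
    while their combined share of the library stays small, so a
    multiplicative spike changes the count composition only marginally.
    """
    rng = np.random.default_rng(spec.seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    rel = base / base.sum()
    median_lib = 0.5 * (spec.library_size_range[0] + spec.library_size_range[1])
    lo, hi = expected_count_range
    band = np.flatnonzero((rel * median_lib >= lo) & (rel * median_lib <= hi))
    if band.size < n:
        raise ValueError(
            f"only {band.size} genes fall in the expected-count band {lo}..{hi}"
        )
    chosen = rng.choice(band, size=n, replace=False)
    return [f"gene{i}" for i in chosen]


def make_deg_pair(
    spec: SynthSpec,
    shifted_genes: Sequence[str] | Sequence[int] = (),
    fold: float = 4.0,
    n_query: int = 10,
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict]:
    """Homogeneous reference cluster plus query cells with known shifted genes.

    Reference cells all share one mean expression vector; query cells use
    the same vector except that ``shifted_genes`` are multiplied by ``fold``
    (library sizes are redrawn from the same range).  The returned truth
    dict lists the shifted genes and the direction of each shift.
    """
    rng = np.random.default_rng(spec.seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    gene_names = [f"gene{i}" for i in range(spec.n_genes)]
    name_to_idx = {g: i for i, g in enumerate(gene_names)}
    shifted_idx = np.array(
        [name_to_idx[g] if isinstance(g, str) else int(g) for g in shifted_genes],
        dtype=np.int64,
    )

    lib_lo, lib_hi = spec.library_size_range
    ref_libs = rng.integers(lib_lo, lib_hi + 1, size=spec.n_cells)
    ref = np.empty((spec.n_genes, spec.n_cells), dtype=np.int64)
    rel = base / base.sum()
    for j in range(spec.n_cells):
        ref[:, j] = _sample_counts(rng, rel * ref_libs[j], spec)

    qmean = base.copy()
    if shifted_idx.size:
        qmean[shifted_idx] *= fold
    qrel = qmean / qmean.sum()
    q_libs = rng.integers(lib_lo, lib_hi + 1, size=n_query)
    query = np.empty((spec.n_genes, n_query), dtype=np.int64)
    for j in range(n_query):
        query[:, j] = _sample_counts(rng, qrel * q_libs[j], spec)

    ref_mat = ExpressionMatrix(
        counts=ref, gene_names=gene_names,
        cell_names=[f"ref{j}" for j in range(spec.n_cells)],
    )
    q_mat = ExpressionMatrix(
        counts=query, gene_names=gene_names,
        cell_names=[f"query{j}" for j in range(n_query)],
    )
    truth = {
        "shifted_genes": [gene_names[i] for i in shifted_idx],
        "fold": fold,
        "direction": "positive" if fold > 1 else ("negative" if fold < 1 else "null"),
        "reference_mean": rel,
    }
    return ref_mat, q_mat, truth
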