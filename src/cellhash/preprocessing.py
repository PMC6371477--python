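"""Five-step preprocessing of UMI count matrices.

Reference cells are prepared for hashing by (1) feature selection on
per-gene maximum counts, (2) cell-wise library-size normalization to a
common total, (3) a variance-stabilizing transform (log(x+1) or the
Freeman-Tukey transform sqrt(x) + sqrt(x+1)), (4) per-feature
standardization to zero mean and unit variance, and (5) projection onto the
top-D singular subspace computed by randomized SVD.  Query cells are pushed
through the identical pipeline reusing the *reference* feature list,
standardization statistics and projection ("folding-in"), which projects
them onto the subspace of reference variability and mitigates batch
effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ExpressionMatrix, align_genes
from .rsvd import randomized_svd

__all__ = [
    "PreprocessorConfig",
    "CellPreprocessor",
    "select_features",
    "normalize_cells",
    "transform_counts",
    "fit_preprocessor",
    "apply_preprocessor",
]

_SD_FLOOR = 1e-8


@dataclass
class PreprocessorConfig:
    """Tunable knobs of the preprocessing pipeline.

    min_features_fraction is the floor on the fraction of genes retained by
    feature selection (default 0.10); n_dims is the dimensionality D of the
    reduced space (default 50); scale_factor is the common post-normalization
    library size (default 10,000 counts per cell).
    """

    min_features_fraction: float = 0.10
    transform: str = "log1p"  # or "ftt"
    n_dims: int = 50
    keep_genes: Optional[Sequence[str]] = None
    drop_genes: Optional[Sequence[str]] = None
    scale_factor: float = 1e4
    n_oversamples: int = 10
    n_power_iters: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.min_features_fraction <= 1:
            raise ValueError("min_features_fraction must lie in (0, 1]")
        if self.transform not in ("log1p", "ftt"):
            raise ValueError("transform must be 'log1p' or 'ftt'")
        if self.n_dims < 1:
            raise ValueError("n_dims must be positive")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")


def select_features(X: ExpressionMatrix, config: PreprocessorConfig) -> list[str]:
    """Genes whose maximum count across cells clears an adaptive threshold.

    The threshold t is the largest integer such that at least
    ``ceil(min_features_fraction * n_genes)`` genes have max count >= t;
    keep_genes/drop_genes overrides are applied afterwards.
    """
    if X.n_genes == 0 or X.n_cells == 0:
        raise ValueError("empty expression matrix")
    counts = sp.csr_matrix(X.counts)
    maxima = np.asarray(counts.max(axis=1).todense()).ravel()
    floor = int(np.ceil(config.min_features_fraction * X.n_genes))
    floor = max(floor, 1)
    # survivors(t) = #{g : max_g >= t} is non-increasing in t, so the largest
    # feasible t is the floor-th largest per-gene maximum.
    t = int(np.sort(maxima)[::-1][floor - 1])
    if config.min_features_fraction >= 1.0:
        t = 0
    keep = set(config.keep_genes or ())
    drop = set(config.drop_genes or ())
    selected = [
        g
        for g, mx in zip(X.gene_names, maxima)
        if (mx >= t or g in keep) and g not in drop
    ]
    if not selected:
        raise ValueError("feature selection excluded every gene")
    return selected


def normalize_cells(X: np.ndarray | sp.spmatrix, scale_factor: float = 1e4) -> np.ndarray:
    """Scale each column (cell) so its total count equals ``scale_factor``."""
    dense = np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)
    totals = dense.sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(f"cell at column {int(zero[0])} has zero total count")
    return dense * (scale_factor / totals)


def transform_counts(Y: np.ndarray, transform: str = "log1p") -> np.ndarray:
    """Variance-stabilizing transform: log(x+1) or sqrt(x) + sqrt(x+1)."""
    Y = np.asarray(Y, dtype=np.float64)
    if (Y < 0).any():
        raise ValueError("negative values cannot be transformed")
    if transform == "log1p":
        return np.log1p(Y)
    if transform == "ftt":
        return np.sqrt(Y) + np.sqrt(Y + 1.0)
    raise ValueError("transform must be 'log1p' or 'ftt'")


class CellPreprocessor(TransformerMixin, BaseEstimator):
    """Fitted preprocessing pipeline mapping raw counts to the reduced space.

    Scikit-learn style transformer.  ``fit`` expects reference cells, either
    as an :class:`ExpressionMatrix` (genes x cells) or as an array of shape
    (n_cells, n_genes) with ``gene_names`` supplied; ``transform`` maps query
    cells to the D-dimensional reduced space, reusing the reference feature
    list, standardization statistics and projection.

    Attributes (after fit)
    ----------------------
    selected_genes_ : list of retained gene names, in reference order.
    feature_means_, feature_sds_ : per-feature statistics on the transformed
        scale (unbiased n-1 variance); sds are all > 1e-8.
    projection_ : (n_dims, n_selected) matrix whose rows are the top-D
        left-singular directions of the standardized reference matrix.
    reduced_ : (n_dims, n_cells) reduced reference matrix from the fit.
    """

    def __init__(
        self,
        min_features_fraction: float = 0.10,
        count_transform: str = "log1p",
        n_dims: int = 50,
        keep_genes: Optional[Sequence[str]] = None,
        drop_genes: Optional[Sequence[str]] = None,
        scale_factor: float = 1e4,
        n_oversamples: int = 10,
        n_power_iters: int = 3,
        random_state: int = 0,
    ):
        self.min_features_fraction = min_features_fraction
        self.count_transform = count_transform
        self.n_dims = n_dims
        self.keep_genes = keep_genes
        self.drop_genes = drop_genes
        self.scale_factor = scale_factor
        self.n_oversamples = n_oversamples
        self.n_power_iters = n_power_iters
        self.random_state = random_state

    def _config(self) -> PreprocessorConfig:
        return PreprocessorConfig(
            min_features_fraction=self.min_features_fraction,
            transform=self.count_transform,
            n_dims=self.n_dims,
            keep_genes=self.keep_genes,
            drop_genes=self.drop_genes,
            scale_factor=self.scale_factor,
            n_oversamples=self.n_oversamples,
            n_power_iters=self.n_power_iters,
        )

    def _coerce(self, X, gene_names=None) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        arr = sp.csr_matrix(X) if sp.issparse(X) else np.asarray(X)
        n_cells, n_genes = arr.shape
        if gene_names is None:
            gene_names = [f"gene{i}" for i in range(n_genes)]
        cells = [f"cell{j}" for j in range(n_cells)]
        return ExpressionMatrix(counts=arr.T, gene_names=list(gene_names), cell_names=cells)

    def fit(self, X, y=None, gene_names=None):
        """Fit on reference cells and cache their reduced matrix."""
        self.fit_transform(X, y, gene_names=gene_names)
        return self

    def fit_transform(self, X, y=None, gene_names=None) -> np.ndarray:
        X = self._coerce(X, gene_names)
        config = self._config()
        if X.n_cells < 2:
            raise ValueError("at least two reference cells are required")
        selected = select_features(X, config)

        # Zero-variance features on the transformed scale are dropped and the
        # normalization/statistics recomputed on the final set, so reference
        # and query cells are always normalized over the same genes.
        frame = X.to_frame()
        for _ in range(X.n_genes):
            sub = frame.loc[selected].to_numpy()
            norm = normalize_cells(sub, config.scale_factor)
            trans = transform_counts(norm, config.transform)
            means = trans.mean(axis=1)
            sds = trans.std(axis=1, ddof=1)
            degenerate = sds < _SD_FLOOR
            if not degenerate.any():
                break
            warnings.warn(
                f"dropping {int(degenerate.sum())} zero-variance feature(s)",
                stacklevel=2,
            )
            selected = [g for g, bad in zip(selected, degenerate) if not bad]
            if not selected:
                raise ValueError("all selected features have zero variance")
        if len(selected) < config.n_dims:
            raise ValueError(
                f"only {len(selected)} features survive selection but "
                f"n_dims={config.n_dims}"
            )
        standardized = (trans - means[:, None]) / sds[:, None]
        svd = randomized_svd(
            standardized,
            rank=config.n_dims,
            n_oversamples=config.n_oversamples,
            n_power_iters=config.n_power_iters,
            rng_seed=int(self.random_state) % (2**31),
        )
        self.selected_genes_ = selected
        self.feature_means_ = means
        self.feature_sds_ = sds
        self.projection_ = svd.U.T  # (D, n_selected)
        self.singular_values_ = svd.S
        self.reduced_ = self.projection_ @ standardized  # (D, N)
        self.n_features_in_ = X.n_genes
        return self.reduced_

    def transform(self, X, gene_names=None, query_stats: bool = False) -> np.ndarray:
        """Map query cells to the reduced space (D x n_query).

        With ``query_stats`` the standardization statistics are estimated
        from the query itself instead of the reference — useful when query
        and reference come from different species or otherwise incomparable
        scales.
        """
        check_is_fitted(self, "projection_")
        X = self._coerce(X, gene_names)
        aligned = align_genes(X, self.selected_genes_)
        norm = normalize_cells(aligned.counts, self.scale_factor)
        trans = transform_counts(norm, self.count_transform)
        if query_stats:
            if aligned.n_cells < 2:
                raise ValueError("query_stats requires at least two query cells")
            means = trans.mean(axis=1)
            sds = trans.std(axis=1, ddof=1)
            sds = np.where(sds < _SD_FLOOR, 1.0, sds)
        else:
            means, sds = self.feature_means_, self.feature_sds_
        standardized = (trans - means[:, None]) / sds[:, None]
        return self.projection_ @ standardized


def fit_preprocessor(
    X: ExpressionMatrix, config: Optional[PreprocessorConfig] = None, rng_seed: int = 0
) -> tuple[CellPreprocessor, np.ndarray]:
    """Fit the pipeline on reference cells; returns (preprocessor, D x N matrix)."""
    config = config or PreprocessorConfig()
    prep = CellPreprocessor(
        min_features_fraction=config.min_features_fraction,
        count_transform=config.transform,
        n_dims=config.n_dims,
        keep_genes=config.keep_genes,
        drop_genes=config.drop_genes,
        scale_factor=config.scale_factor,
        n_oversamples=config.n_oversamples,
        n_power_iters=config.n_power_iters,
        random_state=rng_seed,
    )
    reduced = prep.fit_transform(X)
    return prep, reduced


def apply_preprocessor(
    P: CellPreprocessor, Q: ExpressionMatrix, query_stats: bool = False
) -> np.ndarray:
    """Apply a fitted pipeline to query cells (folding-in)."""
    return P.transform(Q, query_stats=query_stats)
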