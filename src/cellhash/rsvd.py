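"""Randomized truncated singular value decomposition.

Dimensionality reduction of expression matrices only needs the subspace
spanned by the top few dozen singular vectors, so a full decomposition is
wasteful.  The range-finder algorithm implemented here draws a Gaussian test
matrix, runs a few power iterations with re-orthonormalization to sharpen
the captured spectrum, and then decomposes the small projected matrix
exactly.  An optional per-row offset lets callers decompose a centered
matrix ``A - mu 1^T`` without materializing it, which keeps sparse inputs
sparse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg
import scipy.sparse as sp

__all__ = ["SVDResult", "randomized_svd"]


@dataclass
class SVDResult:
    """Truncated SVD: ``A ~= U @ diag(S) @ V.T``.

    ``U`` is (M, D), ``S`` is length D and non-increasing, ``V`` is (N, D);
    columns of U and V are orthonormal.
    """

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray


class _OffsetMatrix:
    """Implicit representation of ``A - offset @ 1^T`` (offset per row)."""

    def __init__(self, A, offset: Optional[np.ndarray]):
        self.A = A
        self.offset = None if offset is None else np.asarray(offset, dtype=np.float64)
        if self.offset is not None and self.offset.shape != (A.shape[0],):
            raise ValueError("row offset length must equal the number of rows")

    @property
    def shape(self):
        return self.A.shape

    def matmat(self, X: np.ndarray) -> np.ndarray:
        Y = self.A @ X
        Y = np.asarray(Y)
        if self.offset is not None:
            Y -= np.outer(self.offset, X.sum(axis=0))
        return Y

    def rmatmat(self, X: np.ndarray) -> np.ndarray:
        # (A - mu 1^T)^T X = A^T X - 1 (mu^T X)
        Y = self.A.T @ X
        Y = np.asarray(Y)
        if self.offset is not None:
            Y -= np.broadcast_to(self.offset @ X, (self.A.shape[1], X.shape[1]))
        return Y


def randomized_svd(
    A,
    rank: int,
    n_oversamples: int = 10,
    n_power_iters: int = 3,
    rng_seed: int = 0,
    row_offset: Optional[np.ndarray] = None,
) -> SVDResult:
    """Approximate the top ``rank`` singular triplets of ``A``.

    Parameters
    ----------
    A
        Real matrix (dense or scipy sparse).
    rank
        Number of singular triplets to return; at most ``min(A.shape)``.
    n_oversamples
        Extra columns in the Gaussian test matrix; improves accuracy at
        negligible cost.
    n_power_iters
        Subspace (power) iterations, re-orthonormalized by QR each pass.
    rng_seed
        Seed for the Gaussian test matrix; fixes the result exactly.
    row_offset
        Optional vector ``mu``: decompose ``A - mu 1^T`` implicitly.
    """
    m, n = A.shape
    if rank < 1 or rank > min(m, n):
        raise ValueError(f"rank must be in [1, {min(m, n)}], got {rank}")
    op = _OffsetMatrix(A, row_offset)
    rng = np.random.default_rng(rng_seed)
    ell = min(rank + n_oversamples, min(m, n))

    Omega = rng.standard_normal((n, ell))
    Q = np.linalg.qr(op.matmat(Omega))[0]
    for _ in range(n_power_iters):
        Q = np.linalg.qr(op.rmatmat(Q))[0]
        Q = np.linalg.qr(op.matmat(Q))[0]

    B = op.rmatmat(Q).T  # (ell, n)
    Ub, S, Vt = scipy.linalg.svd(B, full_matrices=False)
    U = Q @ Ub
    return SVDResult(U=U[:, :rank], S=S[:rank], V=Vt[:rank].T)
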