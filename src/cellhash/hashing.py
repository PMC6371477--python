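"""Signed-random-projection locality-sensitive hashing.

Each of T hash bits is the sign of a dot product with a random hyperplane
normal drawn from the standard isotropic Gaussian.  For two profiles x and
y the collision probability of one bit is 1 - theta(x, y)/pi, so the
Hamming distance between their T-bit codes is an unbiased estimator of the
angle (scaled by pi/T) and hence of the cosine similarity.  Orthogonalizing
the normals within batches of at most D vectors (QR decomposition) removes
linear dependency among hyperplanes and reduces the estimator variance
without introducing bias.

Bit layout: bit i of a code corresponds to hyperplane i and is stored
little-endian within 64-bit words (word ``i // 64``, bit ``i % 64``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HyperplaneSet",
    "BitCodes",
    "generate_hyperplanes",
    "encode",
    "pack_bits",
    "unpack_bits",
    "hamming_distance",
    "estimate_angle",
    "cosine_from_hamming",
]


@dataclass
class HyperplaneSet:
    """T hyperplane normals of length D (one per row)."""

    normals: np.ndarray  # (T, D) float64
    rng_seed: int
    orthogonalized: bool = True

    @property
    def n_bits(self) -> int:
        return self.normals.shape[0]

    @property
    def n_dims(self) -> int:
        return self.normals.shape[1]


@dataclass
class BitCodes:
    """N packed bit vectors of length T."""

    words: np.ndarray  # (N, ceil(T/64)) uint64
    n_bits: int

    @property
    def n_codes(self) -> int:
        return self.words.shape[0]

    @property
    def n_words(self) -> int:
        return self.words.shape[1]

    def __getitem__(self, i) -> np.ndarray:
        return self.words[i]


def generate_hyperplanes(
    D: int, T: int, orthogonalize: bool = True, rng_seed: int = 0
) -> HyperplaneSet:
    """Draw T Gaussian hyperplane normals of length D.

    With ``orthogonalize`` the rows are processed in ``ceil(T/D)`` batches of
    at most D rows and each batch is orthonormalized by QR (signs fixed so
    the result is reproducible across LAPACK builds).  Rows in different
    batches remain independent draws.
    """
    if D < 1 or T < 1:
        raise ValueError("D and T must be positive")
    rng = np.random.default_rng(rng_seed)
    normals = rng.standard_normal((T, D))
    if orthogonalize:
        for start in range(0, T, D):
            batch = normals[start : start + D]  # (b, D), b <= D
            Q, R = np.linalg.qr(batch.T)  # Q: (D, b)
            signs = np.sign(np.diag(R))
            signs[signs == 0] = 1.0
            normals[start : start + D] = (Q * signs).T
    return HyperplaneSet(normals=normals, rng_seed=rng_seed, orthogonalized=orthogonalize)


def pack_bits(bits: np.ndarray) -> np.ndarray:
    """Pack a boolean (N, T) array into (N, ceil(T/64)) uint64 words."""
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.ndim != 2:
        raise ValueError("expected a 2-d bit array")
    n, t = bits.shape
    n_words = (t + 63) // 64
    padded = np.zeros((n, n_words * 64), dtype=np.uint8)
    padded[:, :t] = bits
    packed = np.packbits(padded, axis=1, bitorder="little")
    return packed.view("<u8").reshape(n, n_words)


def unpack_bits(codes: BitCodes) -> np.ndarray:
    """Inverse of :func:`pack_bits`; returns a boolean (N, T) array."""
    as_bytes = codes.words.astype("<u8").view(np.uint8).reshape(codes.n_codes, -1)
    bits = np.unpackbits(as_bytes, axis=1, bitorder="little")
    return bits[:, : codes.n_bits].astype(bool)


def encode(X: np.ndarray, H: HyperplaneSet) -> BitCodes:
    """Hash the columns of a D x N matrix into N bit vectors of length T.

    Bit i of cell j is 1 iff the projection of column j onto normal i is
    strictly positive (an exactly-zero projection maps to 0, fixing the
    measure-zero tie deterministically).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != H.n_dims:
        raise ValueError(
            f"expected input with {H.n_dims} rows, got shape {X.shape}"
        )
    bits = (H.normals @ X) > 0  # (T, N)
    return BitCodes(words=pack_bits(bits.T), n_bits=H.n_bits)


def hamming_distance(query_words: np.ndarray, words: np.ndarray) -> np.ndarray:
    """Hamming distances between one packed code and an (N, W) code array."""
    return np.bitwise_count(words ^ query_words).sum(axis=-1).astype(np.int64)


def estimate_angle(d_H: int | np.ndarray, T_total: int) -> float | np.ndarray:
    """Angle estimate (radians) from a Hamming distance over T_total bits."""
    d = np.asarray(d_H)
    if np.any(d < 0) or np.any(d > T_total):
        raise ValueError(f"Hamming distance must lie in [0, {T_total}]")
    out = np.pi * d / T_total
    return float(out) if np.isscalar(d_H) else out


def cosine_from_hamming(d_H: int | np.ndarray, T_total: int) -> float | np.ndarray:
    """Cosine-similarity estimate from a (total) Hamming distance.

    When L independent hash indexes are aggregated, ``T_total`` is T*L and
    ``d_H`` is the total Hamming distance summed over the L codes.
    """
    out = np.cos(estimate_angle(d_H, T_total))
    return float(out) if np.isscalar(d_H) else out
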