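"""Exact k-nearest-neighbor search in Hamming space via multi-index hashing.

A T-bit code is split into m contiguous blocks of at most s bits and each
block is indexed by a direct-address table.  A query is answered by
progressively growing a per-block probe radius r': at radius r' every
subcode within r' bit flips of the query's subcode is looked up in the
corresponding block table, candidates are verified by their full Hamming
distance, and the search stops as soon as the pigeonhole bound guarantees
completeness — any code not yet seen must differ by more than r' bits in
every block, hence its full distance is at least m * (r' + 1).  The result
is therefore identical to a brute-force scan (up to the ordering of
equal-distance ties, which are broken by ascending database position).

Each block's table is the sparse direct-address structure made of three
arrays: ``filled`` (a 2^s-bit occupancy bit vector supporting ranked
popcount), ``offsets`` (per occupied subcode, the slice bounds into
``buckets``), and ``buckets`` (database positions grouped by subcode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np

from .hashing import BitCodes, hamming_distance

__all__ = [
    "SubIndex",
    "MultiIndexHash",
    "build_mih",
    "knn_search",
    "search_space_size",
    "default_subcode_bits",
]


def search_space_size(T: int, r: int) -> int:
    """Number of single-table buckets within Hamming radius r of a query.

    Exact arbitrary-precision value of ``sum_{i=0..r} C(T, i)`` — the count
    that makes naive radius search infeasible for long codes and motivates
    splitting codes into blocks.
    """
    if not 0 <= r <= T:
        raise ValueError(f"radius must lie in [0, {T}]")
    return sum(math.comb(T, i) for i in range(r + 1))


def default_subcode_bits(n: int) -> int:
    """Default block width: ~log2(N) bits, clamped to [8, 16].

    Keeps expected bucket occupancy near one while bounding the occupancy
    bit vector at 2^16 entries.
    """
    return int(np.clip(int(math.log2(max(n, 2))), 8, 16))


@dataclass
class SubIndex:
    """Sparse direct-address table over one block of subcodes."""

    s: int  # subcode length in bits
    filled: np.ndarray  # (ceil(2^s / 64),) uint64 occupancy bits
    word_rank: np.ndarray  # cumulative popcount of filled words (exclusive)
    offsets: np.ndarray  # (n_occupied + 1,) int64
    buckets: np.ndarray  # (N,) int64 database positions grouped by subcode

    @classmethod
    def build(cls, values: np.ndarray, s: int) -> "SubIndex":
        n_slots = 1 << s
        values = np.asarray(values, dtype=np.uint64)
        order = np.argsort(values, kind="stable")
        sorted_vals = values[order]
        occupied, counts = np.unique(sorted_vals, return_counts=True)
        filled = np.zeros(((n_slots + 63) // 64,), dtype=np.uint64)
        # ufunc.at handles several occupied subcodes falling in one word
        np.bitwise_or.at(
            filled, (occupied >> np.uint64(6)).astype(np.int64),
            np.uint64(1) << (occupied & np.uint64(63)),
        )
        word_rank = np.zeros(filled.shape[0] + 1, dtype=np.int64)
        np.cumsum(np.bitwise_count(filled), out=word_rank[1:])
        offsets = np.zeros(occupied.shape[0] + 1, dtype=np.int64)
        np.cumsum(counts, out=offsets[1:])
        return cls(
            s=s,
            filled=filled,
            word_rank=word_rank,
            offsets=offsets,
            buckets=order.astype(np.int64),
        )

    def lookup_many(self, values: np.ndarray) -> np.ndarray:
        """Database positions whose subcode equals any of ``values``."""
        values = np.asarray(values, dtype=np.uint64)
        word = (values >> np.uint64(6)).astype(np.int64)
        bit = values & np.uint64(63)
        wvals = self.filled[word]
        present = (wvals >> bit) & np.uint64(1) != 0
        if not present.any():
            return np.empty(0, dtype=np.int64)
        word = word[present]
        bit = bit[present]
        wvals = wvals[present]
        below = np.bitwise_count(wvals & ((np.uint64(1) << bit) - np.uint64(1)))
        rank = self.word_rank[word] + below.astype(np.int64)
        starts = self.offsets[rank]
        stops = self.offsets[rank + 1]
        total = int((stops - starts).sum())
        out = np.empty(total, dtype=np.int64)
        pos = 0
        for a, b in zip(starts, stops):
            out[pos : pos + (b - a)] = self.buckets[a:b]
            pos += b - a
        return out


@dataclass
class MultiIndexHash:
    """m block tables plus the packed codes for full-distance verification."""

    codes: BitCodes
    blocks: list[SubIndex]
    bit_ranges: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_codes(self) -> int:
        return self.codes.n_codes

    @property
    def n_bits(self) -> int:
        return self.codes.n_bits


def extract_block(words: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Extract bits [lo, hi) of each packed code as uint64 subcode values."""
    s = hi - lo
    if not 0 < s <= 64:
        raise ValueError("block width must be in (0, 64]")
    w0, off = divmod(lo, 64)
    vals = words[:, w0] >> np.uint64(off)
    if off + s > 64:
        vals = vals | (words[:, w0 + 1] << np.uint64(64 - off))
    if s < 64:
        vals = vals & ((np.uint64(1) << np.uint64(s)) - np.uint64(1))
    return vals


def build_mih(codes: BitCodes, s: int | None = None) -> MultiIndexHash:
    """Index packed codes for exact Hamming k-NN.

    ``s`` is the subcode width in bits (default ``clamp(log2 N, 8, 16)``);
    the code is split into ``ceil(T/s)`` blocks, the last possibly shorter.
    """
    if s is None:
        s = default_subcode_bits(codes.n_codes)
    if not 1 <= s <= min(codes.n_bits, 24):
        raise ValueError(f"subcode width must lie in [1, {min(codes.n_bits, 24)}]")
    T = codes.n_bits
    bit_ranges = [(lo, min(lo + s, T)) for lo in range(0, T, s)]
    blocks = [
        SubIndex.build(extract_block(codes.words, lo, hi), hi - lo)
        for lo, hi in bit_ranges
    ]
    return MultiIndexHash(codes=codes, blocks=blocks, bit_ranges=bit_ranges)


@lru_cache(maxsize=None)
def _flip_masks(s: int, r: int) -> np.ndarray:
    """All XOR masks with exactly r of the low s bits set."""
    if r == 0:
        return np.zeros(1, dtype=np.uint64)
    masks = [
        np.uint64(sum(1 << b for b in bits)) for bits in combinations(range(s), r)
    ]
    return np.array(masks, dtype=np.uint64)


def knn_search(
    index: MultiIndexHash, query: np.ndarray, k: int
) -> list[tuple[int, int]]:
    """Exact k nearest codes to a packed query, as (position, distance).

    Ties at equal distance are ordered by ascending database position; at
    most ``min(k, N)`` pairs are returned.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    n = index.n_codes
    if n == 0:
        raise ValueError("empty index")
    query = np.asarray(query, dtype=np.uint64).reshape(-1)
    if query.shape[0] != index.codes.n_words:
        raise ValueError("query word count does not match the index")
    k_eff = min(k, n)
    m = len(index.blocks)
    qsubs = [
        extract_block(query[None, :], lo, hi)[0] for lo, hi in index.bit_ranges
    ]

    seen = np.zeros(n, dtype=bool)
    cand_pos: list[np.ndarray] = []
    cand_dist: list[np.ndarray] = []
    n_found = 0
    kth_best = np.iinfo(np.int64).max
    max_radius = max(b.s for b in index.blocks)

    for radius in range(0, max_radius + 1):
        for block, qsub in zip(index.blocks, qsubs):
            if radius > block.s:
                continue
            probes = qsub ^ _flip_masks(block.s, radius)
            hits = block.lookup_many(probes)
            if hits.size == 0:
                continue
            new = hits[~seen[hits]]
            if new.size == 0:
                continue
            seen[new] = True
            d = hamming_distance(query, index.codes.words[new])
            cand_pos.append(new)
            cand_dist.append(d)
            n_found += new.size
        if n_found >= k_eff:
            dists = np.concatenate(cand_dist)
            kth_best = np.partition(dists, k_eff - 1)[k_eff - 1]
            # any unseen code differs in > radius bits in every block
            if kth_best < m * (radius + 1):
                break

    pos = np.concatenate(cand_pos)
    dist = np.concatenate(cand_dist)
    order = np.lexsort((pos, dist))[:k_eff]
    return [(int(pos[i]), int(dist[i])) for i in order]
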