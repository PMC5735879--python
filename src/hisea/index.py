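"""k-mer occurrence index over a reference read set.

Every k-mer of every reference read, on both strands, is recorded as a
``(read_id, position, strand)`` occurrence.  Two frequency filters are
applied at build time:

* k-mers whose total occurrence count (summed over reads and strands)
  exceeds ``max_kmer_count`` are dropped — these are repeat-induced and
  would blow up candidate pair generation;
* k-mers occurring fewer than ``min_kmer_count`` times are dropped.  This
  floor is only meaningful in self-overlap mode (reference = query), where
  any k-mer supporting a true overlap necessarily occurs at least twice in
  the set; in two-set mode the caller should leave the floor at 1.

The index is a flat sorted-array structure: occurrence records sorted by
(k-mer value, read_id, strand, position), with a parallel array of unique
k-mer values and slice offsets, so a lookup is one binary search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FORWARD = 0
REVERSE = 1


def kmer_values(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer values of all k-mers of a 2-bit code array.

    The first base is the most significant digit (base-4 big endian).
    Returns an empty array when the sequence is shorter than k.
    """
    n = len(codes)
    if k < 1 or k > 32:
        raise ValueError(f"k must be in [1, 32], got {k}")
    if n < k:
        return np.empty(0, dtype=np.uint64)
    c = codes.astype(np.uint64)
    m = n - k + 1
    vals = np.zeros(m, dtype=np.uint64)
    for j in range(k):  # Horner evaluation, k vector ops
        vals = (vals << np.uint64(2)) | c[j : j + m]
    return vals


def kmer_value_of(seq_codes: np.ndarray) -> int:
    """Value of a single k-mer given as a code array."""
    v = 0
    for c in seq_codes:
        v = (v << 2) | int(c)
    return v


@dataclass(frozen=True)
class IndexParams:
    """Parameters of the reference k-mer index.

    k
        seed length in bases (default 16).
    max_kmer_count
        occurrence ceiling; more frequent k-mers are ignored (default 10000).
    min_kmer_count
        occurrence floor; rarer k-mers are ignored (default 2, applied in
        self-overlap mode — see module docstring).
    """

    k: int = 16
    max_kmer_count: int = 10000
    min_kmer_count: int = 2

    def __post_init__(self):
        if not (0 < self.k <= 32):
            raise ValueError(f"k must be in (0, 32], got {self.k}")
        if self.min_kmer_count < 1:
            raise ValueError("min_kmer_count must be >= 1")
        if self.max_kmer_count < self.min_kmer_count:
            raise ValueError("max_kmer_count must be >= min_kmer_count")


@dataclass
class KmerIndex:
    """Sorted-array index of retained k-mer occurrences (see module docstring)."""

    params: IndexParams
    uniq_values: np.ndarray  # sorted unique retained k-mer values
    offsets: np.ndarray      # len(uniq_values)+1 slice offsets into the arrays below
    read_ids: np.ndarray
    positions: np.ndarray
    strands: np.ndarray
    n_total_kmers: int = 0    # occurrences before filtering
    n_filtered_high: int = 0  # occurrences dropped by the ceiling
    n_filtered_low: int = 0   # occurrences dropped by the floor

    def lookup(self, kmer) -> list[tuple[int, int, int]]:
        """All retained occurrences of a k-mer, ordered (read_id, strand, position).

        ``kmer`` may be a string, a 2-bit code array, or an integer value
        (the latter assumed to already have length ``params.k``).
        """
        value = self._as_value(kmer)
        lo, hi = self.lookup_range(value)
        return [
            (int(self.read_ids[i]), int(self.positions[i]), int(self.strands[i]))
            for i in range(lo, hi)
        ]

    def lookup_range(self, value: int) -> tuple[int, int]:
        """Slice [lo, hi) of the occurrence arrays for a k-mer value."""
        j = int(np.searchsorted(self.uniq_values, np.uint64(value)))
        if j == len(self.uniq_values) or self.uniq_values[j] != np.uint64(value):
            return 0, 0
        return int(self.offsets[j]), int(self.offsets[j + 1])

    def _as_value(self, kmer) -> int:
        from . import seqio

        if isinstance(kmer, (int, np.integer)):
            return int(kmer)
        if isinstance(kmer, str):
            if len(kmer) != self.params.k:
                raise ValueError(
                    f"k-mer length {len(kmer)} != index k {self.params.k}"
                )
            codes = seqio._CODE_TABLE[np.frombuffer(kmer.encode(), dtype=np.uint8)]
            return kmer_value_of(codes)
        codes = np.asarray(kmer)
        if len(codes) != self.params.k:
            raise ValueError(f"k-mer length {len(codes)} != index k {self.params.k}")
        return kmer_value_of(codes)


def build_index(reads, params: IndexParams | None = None) -> KmerIndex:
    """Index all k-mers of both strands of every reference read.

    Reads shorter than k contribute nothing.  Occurrence positions are
    0-based offsets on the strand they annotate (strand 1 positions are on
    the reverse-complement sequence itself).
    """
    if params is None:
        params = IndexParams()
    k = params.k

    vals_parts, rid_parts, pos_parts, strand_parts = [], [], [], []
    for read in reads:
        for strand in (FORWARD, REVERSE):
            vals = kmer_values(read.codes(strand), k)
            if len(vals) == 0:
                continue
            vals_parts.append(vals)
            rid_parts.append(np.full(len(vals), read.read_id, dtype=np.int32))
            pos_parts.append(np.arange(len(vals), dtype=np.int32))
            strand_parts.append(np.full(len(vals), strand, dtype=np.int8))

    if not vals_parts:
        empty = np.empty(0, dtype=np.uint64)
        return KmerIndex(params, empty, np.zeros(1, dtype=np.int64),
                         np.empty(0, np.int32), np.empty(0, np.int32),
                         np.empty(0, np.int8))

    vals = np.concatenate(vals_parts)
    rids = np.concatenate(rid_parts)
    poss = np.concatenate(pos_parts)
    strs = np.concatenate(strand_parts)
    n_total = len(vals)

    # sort by (value, read_id, strand, position): last key primary in lexsort
    order = np.lexsort((poss, strs, rids, vals))
    vals, rids, poss, strs = vals[order], rids[order], poss[order], strs[order]

    uniq, starts, counts = np.unique(vals, return_index=True, return_counts=True)
    keep = counts <= params.max_kmer_count
    n_high = int(counts[~keep].sum())
    low = counts < params.min_kmer_count
    n_low = int(counts[keep & low].sum())
    keep &= ~low

    uniq_k = uniq[keep]
    starts_k = starts[keep]
    counts_k = counts[keep]
    # gather retained occurrence rows
    total = int(counts_k.sum())
    take = np.empty(total, dtype=np.int64)
    offsets = np.zeros(len(uniq_k) + 1, dtype=np.int64)
    np.cumsum(counts_k, out=offsets[1:])
    if total:
        base = np.repeat(starts_k, counts_k)
        within = np.arange(total) - np.repeat(offsets[:-1], counts_k)
        take = base + within

    return KmerIndex(
        params=params,
        uniq_values=uniq_k,
        offsets=offsets,
        read_ids=rids[take],
        positions=poss[take],
        strands=strs[take],
        n_total_kmers=n_total,
        n_filtered_high=n_high,
        n_filtered_low=n_low,
    )


def match_positions(codes_a: np.ndarray, codes_b: np.ndarray, k: int):
    """All exact shared k-mers between two code arrays.

    Returns ``(apos, bpos)`` arrays with one row per (position in a,
    position in b) pair where the k-length substrings are equal, sorted by
    (apos, bpos).  Used for the second-pass small-seed matching inside
    bounded windows.
    """
    va = kmer_values(codes_a, k)
    vb = kmer_values(codes_b, k)
    if len(va) == 0 or len(vb) == 0:
        return (np.empty(0, np.int64), np.empty(0, np.int64))
    order_b = np.argsort(vb, kind="stable")
    vb_sorted = vb[order_b]
    lo = np.searchsorted(vb_sorted, va, side="left")
    hi = np.searchsorted(vb_sorted, va, side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return (np.empty(0, np.int64), np.empty(0, np.int64))
    apos = np.repeat(np.arange(len(va)), counts)
    offsets = np.concatenate(([0], np.cumsum(counts)))
    within = np.arange(total) - np.repeat(offsets[:-1], counts)
    bpos = order_b[np.repeat(lo, counts) + within]
    order = np.lexsort((bpos, apos))
    return apos[order].astype(np.int64), bpos[order].astype(np.int64)
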