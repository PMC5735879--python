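"""Partition seed matches into consistent clusters and apply the binomial filter.

A *consistent* cluster is a maximal run of seed matches whose positions are
non-decreasing on both reads and whose successive position gaps agree up to
the relative indel tolerance ``max_shift``: adjacent matches (q1,r1),(q2,r2)
are consistent iff

    q2 >= q1,  r2 >= r1,  |(q2-q1) - (r2-r1)| <= max_shift * max(q2-q1, r2-r1).

Clustering is a single greedy pass over the match array sorted by
(qpos, rpos); a new cluster starts at the first match inconsistent with its
predecessor.  If no cluster survives selection + the binomial filter, the
pass is retried on the array re-sorted by (rpos, qpos), which can separate
two interleaved chains.

The binomial significance filter models the number of seed hits in an
alignment of length L as Binomial(L, p) with p = (1-e)^(2k) — a k-mer match
survives only if all k bases are error-free on *both* reads.  Clusters with
fewer hits than mu - 3*sigma = L*p - 3*sqrt(L*p*(1-p)) are rejected as too
dissimilar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ChainParams:
    """Clustering / filtering parameters.

    kmer_size
        seed length used to build the matches (default 16).
    max_shift
        relative indel drift tolerance between successive seed gaps
        (default 0.2, i.e. 20%).
    error_rate
        expected per-base error rate of the reads (default 0.15).
    """

    kmer_size: int = 16
    max_shift: float = 0.2
    error_rate: float = 0.15

    def __post_init__(self):
        if not (0 < self.max_shift < 1):
            raise ValueError("max_shift must be in (0, 1)")
        if not (0 < self.error_rate < 1):
            raise ValueError("error_rate must be in (0, 1)")


@dataclass
class Cluster:
    """One consistent run of seed matches.

    ``left_idx``/``right_idx`` delimit the run (inclusive) in the match
    array it was built from; ``matched_bp`` is the number of query bases
    covered by the union of the run's k-mer intervals; ``hit_count`` is the
    number of matches in the run.
    """

    left_idx: int
    right_idx: int
    matched_bp: int
    hit_count: int
    q_lo: int  # leftmost k-mer start on q
    q_hi: int  # rightmost k-mer end on q (exclusive)
    r_lo: int
    r_hi: int


def _covered_bases(starts: np.ndarray, k: int) -> int:
    """Total bases covered by the union of k-length intervals at ``starts``."""
    if len(starts) == 0:
        return 0
    s = np.sort(starts)
    gaps = np.diff(s)
    return int(np.minimum(gaps, k).sum()) + k


def consistent(dq: int, dr: int, max_shift: float) -> bool:
    """Adjacent-pair consistency predicate (see module docstring)."""
    if dq < 0 or dr < 0:
        return False
    return abs(dq - dr) <= max_shift * max(dq, dr)


def cluster_matches(qpos, rpos, params: ChainParams) -> list[Cluster]:
    """Greedy partition of a sorted match array into maximal consistent runs.

    ``qpos``/``rpos`` must already be sorted by the caller's chosen key
    ((qpos, rpos) for the first pass, (rpos, qpos) for the retry); the
    consistency predicate itself is symmetric in the two reads.
    """
    qpos = np.asarray(qpos, dtype=np.int64)
    rpos = np.asarray(rpos, dtype=np.int64)
    n = len(qpos)
    if n == 0:
        return []
    k = params.kmer_size

    dq = np.diff(qpos)
    dr = np.diff(rpos)
    ok = (
        (dq >= 0)
        & (dr >= 0)
        & (np.abs(dq - dr) <= params.max_shift * np.maximum(dq, dr))
    )
    breaks = np.nonzero(~ok)[0] + 1
    bounds = np.concatenate(([0], breaks, [n]))

    clusters = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        qs = qpos[lo:hi]
        rs = rpos[lo:hi]
        clusters.append(
            Cluster(
                left_idx=int(lo),
                right_idx=int(hi - 1),
                matched_bp=_covered_bases(qs, k),
                hit_count=int(hi - lo),
                q_lo=int(qs.min()),
                q_hi=int(qs.max()) + k,
                r_lo=int(rs.min()),
                r_hi=int(rs.max()) + k,
            )
        )
    return clusters


def recluster_on_failure(qpos, rpos, params: ChainParams) -> list[Cluster]:
    """Retry clustering with the sort order reversed: (rpos, qpos).

    Invoked when the (qpos, rpos)-sorted pass yields no cluster passing the
    binomial filter; interleaved chains can separate under the other order.
    """
    qpos = np.asarray(qpos, dtype=np.int64)
    rpos = np.asarray(rpos, dtype=np.int64)
    order = np.lexsort((qpos, rpos))
    return cluster_matches(qpos[order], rpos[order], params)


def select_best_cluster(clusters: list[Cluster]) -> Cluster | None:
    """Cluster with the most matched base pairs.

    Ties break toward the larger hit count, then the leftmost position on
    the query.  Returns None for an empty list (no-overlap signal).
    """
    if not clusters:
        return None
    return min(clusters, key=lambda c: (-c.matched_bp, -c.hit_count, c.q_lo))


def binomial_threshold(L: float, e: float, k: int) -> float:
    """Significance floor mu - 3*sigma on seed hits in a length-L alignment.

    p = (1-e)^(2k); threshold = L*p - 3*sqrt(L*p*(1-p)).  A non-positive
    value means no floor applies.
    """
    if L < 1:
        raise ValueError("alignment length must be >= 1")
    if not (0 <= e < 1):
        raise ValueError("error rate must be in [0, 1)")
    p = (1.0 - e) ** (2 * k)
    return L * p - 3.0 * math.sqrt(L * p * (1.0 - p))


def alignment_length(
    q_lo: int, q_hi: int, r_lo: int, r_hi: int, query_size: int, ref_size: int
) -> int:
    """Estimated alignment length from seed bounds.

    The seed region spans [q_lo, q_hi) on the query and [r_lo, r_hi) on the
    reference; the full alignment can extend left by at most
    min(q_lo, r_lo) bases and right by at most
    min(query_size - q_hi, ref_size - r_hi) bases (whichever read ends
    first stops it).  The estimate is the larger seed span plus both
    extensions.  When the query hangs over on the left and the reference on
    the right this reduces to r_hi + (query_size - q_hi), the projected
    end-to-end length on the reference.
    """
    span = max(q_hi - q_lo, r_hi - r_lo)
    left = min(q_lo, r_lo)
    right = min(query_size - q_hi, ref_size - r_hi)
    return span + left + right


def binomial_filter(
    hit_count: int, L: float, params: ChainParams, k: int | None = None
) -> bool:
    """True iff ``hit_count`` meets the mu - 3*sigma floor for length L."""
    kk = params.kmer_size if k is None else k
    return hit_count >= binomial_threshold(L, params.error_rate, kk)
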