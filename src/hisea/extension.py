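"""Boundary extension with a smaller seed and final overlap validation.

The best cluster of k-mer matches delimits a core region that is then
pushed outward using k'-mer matches (k' < k, default 12): shorter seeds
survive the read error process more often, so they can bridge the sparse
outer stretches where no full k-mer survived.  Candidate k'-mer matches
are confined to the maximum alignment window obtained by projecting the
core bounds outward with the indel allowance (1 + max_shift), consumed in
order of proximity to the current boundary, and each addition must keep
the accumulated hit set above the mu - 3*sigma floor (with p = (1-e)^(2k')
and L the currently extended span); a candidate that violates the drift
bound is skipped, and extension stops when the floor fails.

Finally all k'-mer matches across the whole region (core + extensions)
are counted once more against the mu - 3*sigma floor; only pairs passing
this last check are reported, as boundary coordinates only — no base-level
alignment is ever produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import Cluster, binomial_threshold, consistent
from .index import REVERSE, match_positions


@dataclass(frozen=True)
class ExtensionParams:
    """Second-pass seeding parameters.

    small_k
        extension seed length k' (default 12, must be < the primary k).
    max_shift
        relative indel drift tolerance, shared with clustering.
    error_rate
        expected per-base error rate, shared with clustering.
    """

    small_k: int = 12
    max_shift: float = 0.2
    error_rate: float = 0.15


@dataclass
class OverlapRecord:
    """A reported overlap: boundary coordinates plus support statistics.

    All coordinates are 0-based half-open on the *forward* strand of each
    read; ``strand`` is REVERSE when the reference read was
    reverse-complemented for the alignment.  ``score`` is the number of
    query bases covered by supporting seeds; ``identity`` is an estimate
    derived from the k'-mer hit density, not a DP identity.
    """

    query_id: int
    ref_id: int
    strand: int
    q_start: int
    q_end: int
    q_len: int
    r_start: int
    r_end: int
    r_len: int
    total_hits: int
    score: int
    identity: float


def compute_max_bounds(
    q_lo: int,
    r_lo: int,
    q_hi: int,
    r_hi: int,
    query_size: int,
    ref_size: int,
    max_shift: float,
) -> tuple[int, int, int, int]:
    """Maximum alignment window given the core seed bounds.

    Each read's bound is the seed bound pushed outward by the other read's
    overhang inflated by the indel allowance:

        queryStart = q_lo - (1 + max_shift) * r_lo
        queryEnd   = q_hi + (1 + max_shift) * (ref_size - r_hi)
        refStart   = r_lo - (1 + max_shift) * q_lo
        refEnd     = r_hi + (1 + max_shift) * (query_size - q_hi)

    all clamped to [0, read size].  Returns
    (query_start, query_end, ref_start, ref_end).
    """
    f = 1.0 + max_shift
    q_start = max(0, int(np.floor(q_lo - f * r_lo)))
    q_end = min(query_size, int(np.ceil(q_hi + f * (ref_size - r_hi))))
    r_start = max(0, int(np.floor(r_lo - f * q_lo)))
    r_end = min(ref_size, int(np.ceil(r_hi + f * (query_size - q_hi))))
    return q_start, q_end, r_start, r_end


def _extend_side(
    q_codes: np.ndarray,
    r_codes: np.ndarray,
    boundary: tuple[int, int],
    window: tuple[int, int, int, int],
    params: ExtensionParams,
    left: bool,
) -> tuple[int, int, int]:
    """Push one boundary outward; returns (new_q, new_r, accepted hits).

    ``boundary`` is (q, r): for the left side the start coordinates of the
    core region, for the right side its end coordinates.  ``window`` is
    (wq_lo, wq_hi, wr_lo, wr_hi), the slice of each read in which k'-mer
    candidates are enumerated.
    """
    kp = params.small_k
    bq, br = boundary
    wq_lo, wq_hi, wr_lo, wr_hi = window
    if wq_hi - wq_lo < kp or wr_hi - wr_lo < kp:
        return bq, br, 0

    aq, ar = match_positions(q_codes[wq_lo:wq_hi], r_codes[wr_lo:wr_hi], kp)
    if len(aq) == 0:
        return bq, br, 0
    aq = aq + wq_lo
    ar = ar + wr_lo

    if left:
        keep = (aq <= bq) & (ar <= br)
        dist = (bq - aq) + (br - ar)
    else:
        keep = (aq + kp >= bq) & (ar + kp >= br)
        dist = (aq + kp - bq) + (ar + kp - br)
    aq, ar, dist = aq[keep], ar[keep], dist[keep]
    if len(aq) == 0:
        return bq, br, 0
    order = np.lexsort((ar, aq, dist))
    aq, ar = aq[order], ar[order]

    cq, cr = bq, br  # current boundary
    hits = 0
    for q, r in zip(aq, ar):
        if left:
            dq, dr = cq - int(q), cr - int(r)
        else:
            dq, dr = int(q) + kp - cq, int(r) + kp - cr
        if dq == 0 and dr == 0:
            hits += 1
            continue
        if not consistent(dq, dr, params.max_shift):
            continue  # off-diagonal candidate: skipped, not terminal
        if left:
            new_q, new_r = int(q), int(r)
            span = max(bq - new_q, br - new_r) + kp
        else:
            new_q, new_r = int(q) + kp, int(r) + kp
            span = max(new_q - bq, new_r - br) + kp
        if hits + 1 < binomial_threshold(span, params.error_rate, kp):
            break  # accumulated support no longer significant
        cq, cr = new_q, new_r
        hits += 1
    return cq, cr, hits


def extend_alignment(
    q_codes: np.ndarray,
    r_codes: np.ndarray,
    cluster: Cluster,
    max_bounds: tuple[int, int, int, int],
    params: ExtensionParams,
) -> tuple[int, int, int, int]:
    """Extend the core cluster region on both sides with k'-mer matches.

    Returns the final region (q_start, q_end, r_start, r_end) in
    strand-local coordinates (on the chosen strand of the reference).
    With no usable k'-mer candidates the core bounds are returned
    unchanged.
    """
    kp = params.small_k
    mq_start, mq_end, mr_start, mr_end = max_bounds

    q_start, r_start, _ = _extend_side(
        q_codes,
        r_codes,
        (cluster.q_lo, cluster.r_lo),
        (mq_start, min(cluster.q_lo + kp, len(q_codes)),
         mr_start, min(cluster.r_lo + kp, len(r_codes))),
        params,
        left=True,
    )
    q_end, r_end, _ = _extend_side(
        q_codes,
        r_codes,
        (cluster.q_hi, cluster.r_hi),
        (max(cluster.q_hi - kp, 0), mq_end, max(cluster.r_hi - kp, 0), mr_end),
        params,
        left=False,
    )
    return q_start, q_end, r_start, r_end


def validate_overlap(
    q_codes: np.ndarray,
    r_codes: np.ndarray,
    region: tuple[int, int, int, int],
    params: ExtensionParams,
    query_id: int,
    ref_id: int,
    strand: int,
) -> OverlapRecord | None:
    """Final mu - 3*sigma check over the whole region; emit the record or reject.

    All k'-mer matches inside the final region (deduplicated by position
    pair) are counted; the floor uses p = (1-e)^(2k') and L = the longer
    of the two region spans.  Reference coordinates are flipped to the
    forward strand in the emitted record.
    """
    q_start, q_end, r_start, r_end = region
    kp = params.small_k
    aq, _ar = match_positions(
        q_codes[q_start:q_end], r_codes[r_start:r_end], kp
    )
    total_hits = len(aq)
    L = max(q_end - q_start, r_end - r_start)
    if L < 1 or total_hits < 1:
        return None
    if total_hits < binomial_threshold(L, params.error_rate, kp):
        return None

    matched_bp = 0
    if total_hits:
        s = np.sort(np.unique(aq))
        matched_bp = int(np.minimum(np.diff(s), kp).sum()) + kp

    positions = max(L - kp + 1, 1)
    rate = min(total_hits / positions, 1.0)
    identity = float(rate ** (1.0 / (2 * kp))) if rate > 0 else 0.0

    q_len = len(q_codes)
    r_len = len(r_codes)
    if strand == REVERSE:
        r_start_f, r_end_f = r_len - r_end, r_len - r_start
    else:
        r_start_f, r_end_f = r_start, r_end
    return OverlapRecord(
        query_id=query_id,
        ref_id=ref_id,
        strand=strand,
        q_start=q_start,
        q_end=q_end,
        q_len=q_len,
        r_start=r_start_f,
        r_end=r_end_f,
        r_len=r_len,
        total_hits=total_hits,
        score=matched_bp,
        identity=identity,
    )
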