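"""Candidate seed matching: query k-mers against the reference index.

Query reads are scanned on the forward strand only — reverse-strand
overlaps are captured because the index carries both strands of every
reference read.  For each (query, reference) pair the strand of the
reference with the higher raw k-mer match count is kept; the loser's
matches are discarded.  Matches are deduplicated on (qpos, rpos) and
sorted by (qpos, rpos).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .index import FORWARD, REVERSE, KmerIndex, kmer_values


@dataclass
class MatchList:
    """Seed matches for one (query, reference, strand) pair.

    ``qpos`` are k-mer start positions on the query forward strand;
    ``rpos`` on the chosen strand of the reference (reverse-strand
    positions live on the reverse-complement sequence itself).
    """

    query_id: int
    ref_id: int
    strand: int  # orientation of the reference read: FORWARD or REVERSE
    qpos: np.ndarray
    rpos: np.ndarray

    def __len__(self) -> int:
        return len(self.qpos)


def choose_strand(fwd_count: int, rev_count: int) -> int:
    """Strand with the strictly larger match count; ties go forward."""
    if fwd_count + rev_count < 1:
        raise ValueError("choose_strand requires at least one match")
    return FORWARD if fwd_count >= rev_count else REVERSE


def collect_matches(
    query, index: KmerIndex, self_mode: bool = False
) -> list[MatchList]:
    """One MatchList per reference read sharing >= 1 seed with the query.

    In self-overlap mode (reference set == query set) the pair (q, q) is
    skipped and each unordered pair is produced once, by the read with the
    smaller id; matches to references with id <= query_id are dropped.
    Results are ordered by ref_id.
    """
    k = index.params.k
    qvals = kmer_values(query.codes(FORWARD), k)
    if len(qvals) == 0 or len(index.uniq_values) == 0:
        return []

    j = np.searchsorted(index.uniq_values, qvals)
    j[j == len(index.uniq_values)] = 0
    present = index.uniq_values[j] == qvals
    if not present.any():
        return []
    qpos_hit = np.nonzero(present)[0]
    jj = j[present]
    lo = index.offsets[jj]
    hi = index.offsets[jj + 1]
    counts = (hi - lo).astype(np.int64)
    total = int(counts.sum())
    offsets = np.concatenate(([0], np.cumsum(counts)))
    within = np.arange(total) - np.repeat(offsets[:-1], counts)
    take = np.repeat(lo, counts) + within

    qpos = np.repeat(qpos_hit, counts)
    rid = index.read_ids[take]
    rpos = index.positions[take].astype(np.int64)
    strand = index.strands[take]

    if self_mode:
        mask = rid > query.read_id
        qpos, rid, rpos, strand = qpos[mask], rid[mask], rpos[mask], strand[mask]
        if len(rid) == 0:
            return []

    out: list[MatchList] = []
    for r in np.unique(rid):
        rm = rid == r
        s_r = strand[rm]
        n_fwd = int((s_r == FORWARD).sum())
        n_rev = len(s_r) - n_fwd
        chosen = choose_strand(n_fwd, n_rev)
        sel = rm & (strand == chosen)
        qp, rp = qpos[sel], rpos[sel]
        # sort by (qpos, rpos) and deduplicate
        order = np.lexsort((rp, qp))
        qp, rp = qp[order], rp[order]
        if len(qp) > 1:
            dup = np.zeros(len(qp), dtype=bool)
            dup[1:] = (qp[1:] == qp[:-1]) & (rp[1:] == rp[:-1])
            qp, rp = qp[~dup], rp[~dup]
        out.append(
            MatchList(
                query_id=query.read_id,
                ref_id=int(r),
                strand=int(chosen),
                qpos=qp.astype(np.int64),
                rpos=rp.astype(np.int64),
            )
        )
    return out
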