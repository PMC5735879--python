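"""End-to-end overlap detection pipeline.

Stages, per (query, reference, strand) candidate pair: seed matching
against the reference index -> greedy consistent clustering (with one
retry under the reversed sort order) -> binomial significance filter ->
small-seed boundary extension -> final validation -> M4-dialect record.

Every per-pair computation is a pure function of (query, reference,
configuration); the pipeline is serial and deterministic, and records are
sorted by (query_id, ref_id) before writing, so any future parallel
schedule must reproduce the serial output byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .clustering import (
    ChainParams,
    alignment_length,
    binomial_filter,
    cluster_matches,
    recluster_on_failure,
    select_best_cluster,
)
from .extension import (
    ExtensionParams,
    OverlapRecord,
    compute_max_bounds,
    extend_alignment,
    validate_overlap,
)
from .index import IndexParams, build_index
from .m4 import write_m4
from .matching import MatchList, collect_matches
from .seqio import PackedRead, load_reads

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of an overlapper run.

    ``query_path`` absent means self-overlap mode (all-vs-all within the
    reference set, each unordered pair once).  ``threads`` is accepted for
    interface compatibility; per-pair work is pure so any schedule must
    equal the serial result, and the implementation runs serially.
    ``seed`` is unused by the deterministic pipeline (reserved for the
    simulator).
    """

    ref_path: str
    out_path: str
    query_path: str | None = None
    k: int = 16
    small_k: int = 12
    max_shift: float = 0.2
    error_rate: float = 0.15
    max_kmer_count: int = 10000
    min_kmer_count: int = 2
    min_olap_len: int = 100
    threads: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.small_k < self.k):
            raise ValueError("require 0 < small_k < k")


def overlap_pair(
    query: PackedRead,
    ref: PackedRead,
    matches: MatchList,
    chain: ChainParams,
    ext: ExtensionParams,
) -> OverlapRecord | None:
    """Run clustering, filtering, extension and validation for one pair."""
    q_codes = query.codes(0)
    r_codes = ref.codes(matches.strand)

    best = None
    for attempt in range(2):
        if attempt == 0:
            clusters = cluster_matches(matches.qpos, matches.rpos, chain)
        else:
            clusters = recluster_on_failure(matches.qpos, matches.rpos, chain)
        cand = select_best_cluster(clusters)
        if cand is None:
            return None
        L = alignment_length(
            cand.q_lo, cand.q_hi, cand.r_lo, cand.r_hi, query.length, ref.length
        )
        if binomial_filter(cand.hit_count, L, chain):
            best = cand
            break
    if best is None:
        return None

    bounds = compute_max_bounds(
        best.q_lo, best.r_lo, best.q_hi, best.r_hi,
        query.length, ref.length, chain.max_shift,
    )
    region = extend_alignment(q_codes, r_codes, best, bounds, ext)
    return validate_overlap(
        q_codes, r_codes, region, ext,
        query.read_id, ref.read_id, matches.strand,
    )


def find_overlaps(
    ref_reads: list[PackedRead],
    query_reads: list[PackedRead] | None = None,
    *,
    k: int = 16,
    small_k: int = 12,
    max_shift: float = 0.2,
    error_rate: float = 0.15,
    max_kmer_count: int = 10000,
    min_kmer_count: int = 2,
    min_olap_len: int = 100,
) -> tuple[list[OverlapRecord], dict]:
    """Detect overlaps; the in-memory core of the pipeline.

    ``query_reads=None`` selects self-overlap mode.  In two-set mode the
    low-count k-mer floor is forced to 1: a k-mer supporting a true match
    need only occur once in the reference set, and the floor would silently
    destroy sensitivity there.  Returns (records, run report).
    """
    self_mode = query_reads is None
    queries = ref_reads if self_mode else query_reads
    params = IndexParams(
        k=k,
        max_kmer_count=max_kmer_count,
        min_kmer_count=min_kmer_count if self_mode else 1,
    )
    chain = ChainParams(kmer_size=k, max_shift=max_shift, error_rate=error_rate)
    ext = ExtensionParams(small_k=small_k, max_shift=max_shift, error_rate=error_rate)

    index = build_index(ref_reads, params)
    ref_by_id = {r.read_id: r for r in ref_reads}

    records: list[OverlapRecord] = []
    pairs_examined = 0
    for q in queries:
        for ml in collect_matches(q, index, self_mode=self_mode):
            pairs_examined += 1
            rec = overlap_pair(q, ref_by_id[ml.ref_id], ml, chain, ext)
            if rec is None:
                continue
            if max(rec.q_end - rec.q_start, rec.r_end - rec.r_start) < min_olap_len:
                continue
            records.append(rec)
    records.sort(key=lambda r: (r.query_id, r.ref_id))

    report = {
        "n_ref_reads": len(ref_reads),
        "n_query_reads": len(queries),
        "self_mode": self_mode,
        "kmers_indexed": int(index.n_total_kmers
                             - index.n_filtered_high
                             - index.n_filtered_low),
        "kmers_filtered_high": int(index.n_filtered_high),
        "kmers_filtered_low": int(index.n_filtered_low),
        "pairs_examined": pairs_examined,
        "overlaps_reported": len(records),
    }
    return records, report


def run_overlapper(config: RunConfig) -> dict:
    """File-to-file pipeline entry: read input, detect overlaps, write M4."""
    ref_reads = load_reads(config.ref_path)
    query_reads = (
        load_reads(config.query_path) if config.query_path is not None else None
    )
    if len(ref_reads) == 0:
        logger.warning("reference set %s is empty; writing empty output",
                       config.ref_path)
        write_m4([], config.out_path, [], [])
        return {"n_ref_reads": 0, "overlaps_reported": 0}

    records, report = find_overlaps(
        ref_reads,
        query_reads,
        k=config.k,
        small_k=config.small_k,
        max_shift=config.max_shift,
        error_rate=config.error_rate,
        max_kmer_count=config.max_kmer_count,
        min_kmer_count=config.min_kmer_count,
        min_olap_len=config.min_olap_len,
    )
    ref_names = [r.name for r in ref_reads]
    query_names = (
        ref_names if query_reads is None else [q.name for q in query_reads]
    )
    write_m4(records, config.out_path, query_names, ref_names)
    for key, val in report.items():
        logger.info("%s: %s", key, val)
    return report
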