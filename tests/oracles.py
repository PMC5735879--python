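"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (string scans, quadratic DP,
exhaustive adjacency checks) and shares no code with the package beyond
the reverse-complement helper.
"""

from __future__ import annotations

COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


def naive_index(seqs, k, max_count=10**9, min_count=1):
    """Scan every strand of every read; apply both frequency filters.

    Returns ``{kmer string: [(read_id, position, strand), ...]}`` with
    occurrences ordered (read_id, strand, position).
    """
    occ: dict[str, list[tuple[int, int, int]]] = {}
    for rid, seq in enumerate(seqs):
        for strand, s in enumerate((seq, rc(seq))):
            for pos in range(len(s) - k + 1):
                occ.setdefault(s[pos : pos + k], []).append((rid, pos, strand))
    out = {}
    for kmer, entries in occ.items():
        if min_count <= len(entries) <= max_count:
            out[kmer] = sorted(entries, key=lambda e: (e[0], e[2], e[1]))
    return out


def naive_pair_matches(qseq: str, rseq: str, k: int):
    """All exact shared k-mers between two strings, as (qpos, rpos) pairs."""
    pos_by_kmer: dict[str, list[int]] = {}
    for j in range(len(rseq) - k + 1):
        pos_by_kmer.setdefault(rseq[j : j + k], []).append(j)
    out = []
    for i in range(len(qseq) - k + 1):
        for j in pos_by_kmer.get(qseq[i : i + k], ()):
            out.append((i, j))
    return sorted(out)


def exhaustive_clusters(pairs, max_shift):
    """Partition a sorted match list into maximal consistent runs.

    Pure-Python re-statement of the adjacent-consistency predicate: a run
    breaks at the first pair whose gaps to its predecessor are negative on
    either read or drift apart by more than max_shift times the larger gap.
    """
    runs = []
    current = []
    for q, r in pairs:
        if not current:
            current = [(q, r)]
            continue
        pq, pr = current[-1]
        dq, dr = q - pq, r - pr
        if dq >= 0 and dr >= 0 and abs(dq - dr) <= max_shift * max(dq, dr):
            current.append((q, r))
        else:
            runs.append(current)
            current = [(q, r)]
    if current:
        runs.append(current)
    return runs


def covered_query_bases(pairs, k):
    """Union length of the k-length query intervals of a run."""
    starts = sorted({q for q, _ in pairs})
    total = 0
    for a, b in zip(starts, starts[1:]):
        total += min(b - a, k)
    return total + k


def sw_quadratic(a: str, b: str, match=2, mismatch=-3, gap=-5):
    """Full-matrix local alignment DP; returns (score, end_a, end_b)."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        row = H[i]
        prev = H[i - 1]
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            v = max(0, prev[j - 1] + s, prev[j] + gap, row[j - 1] + gap)
            row[j] = v
            if v > best:
                best, bi, bj = v, i, j
    return best, bi, bj
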