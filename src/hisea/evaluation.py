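"""DP-validated evaluation of reported overlaps.

Reported overlaps are judged against the *optimal* local alignment between
the two reads, computed by Smith-Waterman dynamic programming, rather than
against a third-party mapper's calls.  For a pair with a reported overlap
A_rep, ComputeDP finds the optimal alignment A_opt, checks that it is a
good alignment (long enough and with adequate identity), and then compares
the length, direction, and bounds of A_rep with those of A_opt.

Three estimators sample pairs and aggregate ComputeDP verdicts:

* sensitivity — over true-overlap pairs (from ground truth): fraction
  found and judged correct;
* specificity — over pairs with no true overlap: fraction not reported;
* precision  — over reported pairs (truth-free): fraction DP-validated.

Each offers three correctness modes of increasing strictness: "presence"
(the pair was reported), "length" (the reported length and direction match
A_opt within a relative tolerance), and "bounds" (additionally all four
boundary endpoints match within the tolerance).  The modes are nested, so
bounds-sensitivity <= length-sensitivity <= presence-sensitivity always.

The Smith-Waterman kernel is a numba-compiled linear-memory pass (score
and end cell, then a reverse pass for the start cell); identity over the
optimal interval is measured by edlib global alignment of the two interval
substrings.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from numba import njit

from .extension import OverlapRecord
from .index import FORWARD, REVERSE
from .seqio import PackedRead
from .simulate import true_overlaps

MODES = ("presence", "length", "bounds")


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation parameters.

    min_align_len
        analysis floor: only alignments of at least this length count
        (default 2000 bp).
    trials
        maximum number of pairs sampled per estimate (default 50000).
    bound_tolerance
        relative slack, as a fraction of the optimal alignment length,
        allowed when comparing lengths and bound endpoints (default 0.2).
    mode
        correctness mode: "presence", "length", or "bounds".
    match, mismatch, gap
        Smith-Waterman scoring (BLASR-like defaults +2/-3/-5).
    goodness_identity
        identity floor for A_opt to count as a good alignment.
    """

    min_align_len: int = 2000
    trials: int = 50000
    bound_tolerance: float = 0.2
    mode: str = "bounds"
    match: int = 2
    mismatch: int = -3
    gap: int = -5
    goodness_identity: float = 0.6

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not (0 <= self.bound_tolerance < 1):
            raise ValueError("bound_tolerance must be in [0, 1)")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")


@dataclass
class DPResult:
    """Optimal local alignment: score and 0-based half-open intervals."""

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int


@njit(cache=False)
def _sw_end(a, b, match, mismatch, gap):  # pragma: no cover - numba kernel
    n = len(a)
    m = len(b)
    prev = np.zeros(m + 1, dtype=np.int64)
    cur = np.zeros(m + 1, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        cur[0] = 0
        for j in range(1, m + 1):
            s = match if ai == b[j - 1] else mismatch
            v = prev[j - 1] + s
            t = prev[j] + gap
            if t > v:
                v = t
            t = cur[j - 1] + gap
            if t > v:
                v = t
            if v < 0:
                v = 0
            cur[j] = v
            if v > best:  # strict: first maximum => smallest end coordinates
                best = v
                bi = i
                bj = j
        tmp = prev
        prev = cur
        cur = tmp
    return best, bi, bj


def smith_waterman(
    a: np.ndarray, b: np.ndarray, match: int = 2, mismatch: int = -3, gap: int = -5
) -> DPResult:
    """Optimal local alignment of two 2-bit code arrays.

    Linear gap penalty.  Ties break toward the highest score, then the
    smallest end coordinates (row-major first maximum); the start cell is
    recovered by aligning the reversed prefixes.  A best score of 0 yields
    the empty alignment.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("smith_waterman requires non-empty sequences")
    a8 = np.ascontiguousarray(a, dtype=np.uint8)
    b8 = np.ascontiguousarray(b, dtype=np.uint8)
    score, ei, ej = _sw_end(a8, b8, match, mismatch, gap)
    if score == 0:
        return DPResult(0, 0, 0, 0, 0)
    ra = np.ascontiguousarray(a8[:ei][::-1])
    rb = np.ascontiguousarray(b8[:ej][::-1])
    score2, ri, rj = _sw_end(ra, rb, match, mismatch, gap)
    assert score2 == score
    return DPResult(int(score), ei - ri, ei, ej - rj, ej)


_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def _interval_identity(a_sub: np.ndarray, b_sub: np.ndarray) -> float:
    if len(a_sub) == 0 or len(b_sub) == 0:
        return 0.0
    d = edlib.align(_codes_to_str(a_sub), _codes_to_str(b_sub), mode="NW",
                    task="distance")["editDistance"]
    return 1.0 - d / max(len(a_sub), len(b_sub))


@dataclass
class DPComparison:
    """ComputeDP verdict for one pair."""

    good: bool                 # A_opt passes the length + identity floors
    direction: int             # orientation of A_opt (FORWARD/REVERSE)
    opt_len: int
    opt_q: tuple[int, int]
    opt_r: tuple[int, int]     # forward-strand coordinates
    identity: float
    correct: dict              # mode -> bool; empty when no report was given


def compute_dp(
    query: PackedRead,
    ref: PackedRead,
    reported: OverlapRecord | None,
    config: EvalConfig,
) -> DPComparison:
    """Judge a reported overlap against the optimal local alignment.

    The optimal alignment is computed in both orientations of the
    reference and the higher-scoring one kept (tie toward forward).  With
    ``reported=None`` only the goodness assessment is performed.
    """
    q = query.codes(0)
    res_f = smith_waterman(q, ref.codes(FORWARD), config.match, config.mismatch,
                           config.gap)
    res_r = smith_waterman(q, ref.codes(REVERSE), config.match, config.mismatch,
                           config.gap)
    if res_r.score > res_f.score:
        direction, opt = REVERSE, res_r
    else:
        direction, opt = FORWARD, res_f

    opt_len = max(opt.a_end - opt.a_start, opt.b_end - opt.b_start)
    identity = 0.0
    good = False
    if opt_len >= config.min_align_len:
        identity = _interval_identity(
            query.codes(0)[opt.a_start : opt.a_end],
            ref.codes(direction)[opt.b_start : opt.b_end],
        )
        good = identity >= config.goodness_identity

    # reference interval on the forward strand
    if direction == REVERSE:
        opt_r = (ref.length - opt.b_end, ref.length - opt.b_start)
    else:
        opt_r = (opt.b_start, opt.b_end)

    correct: dict = {}
    if reported is not None and good:
        tol = config.bound_tolerance * opt_len
        rep_len = max(
            reported.q_end - reported.q_start, reported.r_end - reported.r_start
        )
        length_ok = (
            reported.strand == direction
            and abs(rep_len - opt_len) <= tol
        )
        bounds_ok = length_ok and all(
            abs(x - y) <= tol
            for x, y in (
                (reported.q_start, opt.a_start),
                (reported.q_end, opt.a_end),
                (reported.r_start, opt_r[0]),
                (reported.r_end, opt_r[1]),
            )
        )
        correct = {"presence": True, "length": length_ok, "bounds": bounds_ok}
    elif reported is not None:
        correct = {m: False for m in MODES}

    return DPComparison(
        good=good,
        direction=direction,
        opt_len=opt_len,
        opt_q=(opt.a_start, opt.a_end),
        opt_r=opt_r,
        identity=identity,
        correct=correct,
    )


def records_by_pair(records) -> dict:
    """Index OverlapRecords by their unordered (query_id, ref_id) pair."""
    out = {}
    for rec in records:
        key = (min(rec.query_id, rec.ref_id), max(rec.query_id, rec.ref_id))
        out[key] = rec
    return out


def estimate_sensitivity(
    records,
    reads: list[PackedRead],
    truth: pd.DataFrame,
    config: EvalConfig,
    seed: int = 0,
    overlaps: pd.DataFrame | None = None,
) -> tuple[float, int]:
    """Fraction of true-overlap pairs found and judged correct.

    Samples up to ``config.trials`` pairs with true overlap >=
    ``min_align_len`` (uniformly, without replacement).  Pairs whose
    optimal alignment fails the goodness floor are excluded from the
    denominator.  Returns (estimate, pairs assessed); the estimate is NaN
    when nothing is assessable.
    """
    if overlaps is None:
        overlaps = true_overlaps(truth, min_len=config.min_align_len)
    else:
        overlaps = overlaps[overlaps["overlap_len"] >= config.min_align_len]
    n_pairs = len(overlaps)
    if n_pairs == 0:
        return float("nan"), 0
    rng = np.random.default_rng(seed)
    take = (
        rng.choice(n_pairs, size=config.trials, replace=False)
        if n_pairs > config.trials
        else np.arange(n_pairs)
    )
    by_pair = records_by_pair(records)
    by_id = {r.read_id: r for r in reads}

    assessed = 0
    correct = 0
    for idx in take:
        row = overlaps.iloc[int(idx)]
        key = (int(row["id_a"]), int(row["id_b"]))
        rec = by_pair.get(key)
        cmp = compute_dp(by_id[key[0]], by_id[key[1]], rec, config)
        if not cmp.good:
            continue
        assessed += 1
        if rec is not None and cmp.correct.get(config.mode, False):
            correct += 1
    if assessed == 0:
        return float("nan"), 0
    return correct / assessed, assessed


def estimate_specificity(
    records,
    truth: pd.DataFrame,
    config: EvalConfig,
    seed: int = 0,
) -> tuple[float, int]:
    """Fraction of non-overlapping pairs that were (rightly) not reported."""
    n = len(truth)
    if n < 2:
        return float("nan"), 0
    overlapping = set()
    all_olaps = true_overlaps(truth, min_len=1)
    for a, b in zip(all_olaps["id_a"], all_olaps["id_b"]):
        overlapping.add((int(a), int(b)))
    reported = set(records_by_pair(records))

    rng = np.random.default_rng(seed)
    assessed = 0
    not_reported = 0
    attempts = 0
    max_attempts = config.trials * 20
    while assessed < config.trials and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        key = (int(min(i, j)), int(max(i, j)))
        if key in overlapping:
            continue
        assessed += 1
        if key not in reported:
            not_reported += 1
    if assessed == 0:
        return float("nan"), 0
    return not_reported / assessed, assessed


def estimate_precision(
    records,
    reads: list[PackedRead],
    config: EvalConfig,
    seed: int = 0,
) -> tuple[float, int]:
    """Fraction of reported overlaps validated by ComputeDP (truth-free).

    Only reports of length >= ``min_align_len`` are assessed.  A report
    whose optimal alignment fails the goodness floor counts as incorrect.
    """
    eligible = [
        r
        for r in records
        if max(r.q_end - r.q_start, r.r_end - r.r_start) >= config.min_align_len
    ]
    if not eligible:
        return float("nan"), 0
    rng = np.random.default_rng(seed)
    if len(eligible) > config.trials:
        take = rng.choice(len(eligible), size=config.trials, replace=False)
        sample = [eligible[int(i)] for i in take]
    else:
        sample = eligible
    by_id = {r.read_id: r for r in reads}

    correct = 0
    for rec in sample:
        cmp = compute_dp(by_id[rec.query_id], by_id[rec.ref_id], rec, config)
        if cmp.good and cmp.correct.get(config.mode, False):
            correct += 1
    return correct / len(sample), len(sample)


def f1_score(sensitivity: float, precision: float) -> float:
    """Harmonic mean of sensitivity and precision; 0 when both are 0."""
    if sensitivity + precision == 0:
        return 0.0
    return 2.0 * sensitivity * precision / (sensitivity + precision)


def exact_recovery_stats(
    records, truth: pd.DataFrame, min_len: int = 2000
) -> dict:
    """Truth-based exactness check, for error-free simulations.

    Sensitivity: fraction of true pairs (overlap >= min_len) reported with
    exactly matching bounds and orientation.  Precision: fraction of
    reports (length >= min_len) matching a true pair exactly.
    max_bound_error: largest endpoint deviation among reported true pairs.
    """
    eligible = true_overlaps(truth, min_len=min_len)
    all_pairs = true_overlaps(truth, min_len=1)
    by_pair = records_by_pair(records)

    def endpoint_error(row, rec) -> int:
        if rec.strand != int(row["strand"]):
            return max(rec.q_len, rec.r_len)
        return max(
            abs(rec.q_start - int(row["a_start"])),
            abs(rec.q_end - int(row["a_end"])),
            abs(rec.r_start - int(row["b_start"])),
            abs(rec.r_end - int(row["b_end"])),
        )

    found_exact = 0
    max_err = 0
    for _, row in eligible.iterrows():
        rec = by_pair.get((int(row["id_a"]), int(row["id_b"])))
        if rec is None:
            continue
        err = endpoint_error(row, rec)
        max_err = max(max_err, err)
        if err == 0:
            found_exact += 1
    sensitivity = found_exact / len(eligible) if len(eligible) else float("nan")

    truth_rows = {
        (int(r["id_a"]), int(r["id_b"])): r for _, r in all_pairs.iterrows()
    }
    n_assessed = 0
    n_correct = 0
    for key, rec in by_pair.items():
        if max(rec.q_end - rec.q_start, rec.r_end - rec.r_start) < min_len:
            continue
        n_assessed += 1
        row = truth_rows.get(key)
        if row is not None and endpoint_error(row, rec) == 0:
            n_correct += 1
    precision = n_correct / n_assessed if n_assessed else float("nan")

    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "max_bound_error": max_err,
        "n_true_pairs": len(eligible),
        "n_reported": n_assessed,
    }


def write_report(stats: dict, path) -> None:
    """Write an evaluation report as a two-column TSV (metric, value)."""
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for key in sorted(stats):
            fh.write(f"{key}\t{stats[key]}\n")
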