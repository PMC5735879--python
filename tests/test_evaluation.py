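"""Smith-Waterman kernel, ComputeDP comparisons, and the three estimators."""

import dataclasses

import numpy as np
import pytest

from hisea.evaluation import (
    EvalConfig,
    compute_dp,
    estimate_precision,
    estimate_sensitivity,
    estimate_specificity,
    f1_score,
    smith_waterman,
)
from hisea.extension import OverlapRecord
from hisea.pipeline import find_overlaps
from hisea.seqio import reads_from_strings
from hisea.simulate import SimConfig, simulate, true_overlaps

from conftest import random_seq
from oracles import rc, sw_quadratic


def codes(s):
    return reads_from_strings([s])[0].codes(0)


def test_sw_perfect_match():
    res = smith_waterman(codes("ACGT"), codes("ACGT"), 2, -3, -5)
    assert res.score == 8
    assert (res.a_start, res.a_end, res.b_start, res.b_end) == (0, 4, 0, 4)


def test_sw_no_positive_cell():
    res = smith_waterman(codes("AAAA"), codes("TTTT"), 2, -3, -5)
    assert res.score == 0
    assert (res.a_start, res.a_end) == (0, 0)


def test_sw_gap_handling():
    # deleting one base costs one gap: 7 matches * 2 - 5 = 9
    res = smith_waterman(codes("ACGTTACG"), codes("ACGTACG"), 2, -3, -5)
    assert res.score == 9


def test_sw_matches_quadratic_oracle(rng):
    """Scores and end cells agree with an independent full-matrix DP."""
    for _ in range(200):
        a = random_seq(rng, int(rng.integers(10, 60)))
        b = random_seq(rng, int(rng.integers(10, 60)))
        res = smith_waterman(codes(a), codes(b), 2, -3, -5)
        score, ei, ej = sw_quadratic(a, b, 2, -3, -5)
        assert res.score == score
        if score > 0:
            assert (res.a_end, res.b_end) == (ei, ej)


def _record(qid, rid, strand, qs, qe, ql, rs, re_, rl):
    return OverlapRecord(
        query_id=qid, ref_id=rid, strand=strand,
        q_start=qs, q_end=qe, q_len=ql,
        r_start=rs, r_end=re_, r_len=rl,
        total_hits=100, score=100, identity=0.9,
    )


@pytest.fixture(scope="module")
def dp_pair():
    rng = np.random.default_rng(77)
    shared = random_seq(rng, 2500)
    a = shared + random_seq(rng, 1500)
    b = shared + random_seq(rng, 1500)
    reads = reads_from_strings([a, b], names=["a", "b"])
    return reads


def test_compute_dp_correct_in_all_modes(dp_pair):
    a, b = dp_pair
    rec = _record(0, 1, 0, 0, 2500, a.length, 0, 2500, b.length)
    cmp = compute_dp(a, b, rec, EvalConfig())
    assert cmp.good and cmp.direction == 0
    assert cmp.correct == {"presence": True, "length": True, "bounds": True}


def test_compute_dp_direction_mismatch(dp_pair):
    a, b = dp_pair
    rec = _record(0, 1, 1, 0, 2500, a.length, 1500, 4000, b.length)
    cmp = compute_dp(a, b, rec, EvalConfig())
    assert cmp.correct["presence"]
    assert not cmp.correct["length"] and not cmp.correct["bounds"]


def test_compute_dp_shifted_bounds(dp_pair):
    """A shift of 2x the tolerance keeps the length but breaks the bounds."""
    a, b = dp_pair
    shift = 1000  # 2 * 0.2 * 2500
    rec = _record(0, 1, 0, shift, 2500 + shift, a.length,
                  shift, 2500 + shift, b.length)
    cmp = compute_dp(a, b, rec, EvalConfig())
    assert cmp.correct["length"]
    assert not cmp.correct["bounds"]


def test_compute_dp_reverse_orientation(rng):
    shared = random_seq(rng, 2500)
    a = shared + random_seq(rng, 1000)
    b = random_seq(rng, 1000) + rc(shared)
    ra, rb = reads_from_strings([a, b], names=["a", "b"])
    rec = _record(0, 1, 1, 0, 2500, ra.length, 1000, 3500, rb.length)
    cmp = compute_dp(ra, rb, rec, EvalConfig())
    assert cmp.good and cmp.direction == 1
    assert cmp.correct["bounds"]


def test_compute_dp_goodness_floor(rng):
    """Unrelated reads admit no good optimal alignment."""
    ra, rb = reads_from_strings(
        [random_seq(rng, 2500), random_seq(rng, 2500)], names=["a", "b"]
    )
    cmp = compute_dp(ra, rb, None, EvalConfig())
    assert not cmp.good


@pytest.fixture(scope="module")
def noisy_sim():
    sim = simulate(SimConfig(genome_length=40000, coverage=8, error_rate=0.1,
                             read_len_mean=4000, read_len_min=2500,
                             read_len_max=6000, seed=13))
    records, _ = find_overlaps(sim.reads)
    return sim, records


def test_estimates_and_mode_nesting(noisy_sim):
    """bounds <= length <= presence sensitivity on a fixed reported set."""
    sim, records = noisy_sim
    # corrupt a third of the reports to spread the modes apart
    rng = np.random.default_rng(1)
    mutated = []
    for i, rec in enumerate(records):
        if i % 3 == 0:
            span = rec.q_end - rec.q_start
            shift = int(0.6 * span)
            new_end = min(rec.q_len, rec.q_end + shift)
            mutated.append(dataclasses.replace(
                rec, q_start=rec.q_start + shift, q_end=new_end))
        else:
            mutated.append(rec)
    values = {}
    for mode in ("presence", "length", "bounds"):
        cfg = EvalConfig(trials=25, mode=mode)
        values[mode], n = estimate_sensitivity(
            mutated, sim.reads, sim.truth, cfg, seed=5
        )
        assert n > 0 and 0 <= values[mode] <= 1
    assert values["bounds"] <= values["length"] <= values["presence"]


def test_sensitivity_trivial_cases(noisy_sim):
    sim, records = noisy_sim
    cfg = EvalConfig(trials=15, mode="presence")
    empty, n = estimate_sensitivity([], sim.reads, sim.truth, cfg, seed=2)
    assert empty == 0.0 and n > 0
    full, _ = estimate_sensitivity(records, sim.reads, sim.truth, cfg, seed=2)
    assert full == 1.0


def test_estimates_reproducible(noisy_sim):
    sim, records = noisy_sim
    cfg = EvalConfig(trials=10, mode="bounds")
    a = estimate_sensitivity(records, sim.reads, sim.truth, cfg, seed=11)
    b = estimate_sensitivity(records, sim.reads, sim.truth, cfg, seed=11)
    assert a == b


def test_specificity(noisy_sim):
    sim, records = noisy_sim
    cfg = EvalConfig(trials=300)
    spec, n = estimate_specificity(records, sim.truth, cfg, seed=4)
    assert n == 300
    assert spec == 1.0  # nothing spurious on this fixture
    none, _ = estimate_specificity([], sim.truth, cfg, seed=4)
    assert none == 1.0


def test_precision(noisy_sim):
    sim, records = noisy_sim
    cfg = EvalConfig(trials=20, mode="bounds")
    prec, n = estimate_precision(records, sim.reads, cfg, seed=6)
    assert n == 20
    assert prec >= 0.9


@pytest.mark.parametrize(
    "s,p,expected",
    [(1, 1, 1.0), (0, 0.5, 0.0), (0, 0, 0.0), (0.8, 0.6, 0.6857)],
)
def test_f1(s, p, expected):
    assert f1_score(s, p) == pytest.approx(expected, abs=1e-4)
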