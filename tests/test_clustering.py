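"""Consistent-run clustering, cluster selection, and the binomial filter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hisea.clustering import (
    ChainParams,
    alignment_length,
    binomial_filter,
    binomial_threshold,
    cluster_matches,
    recluster_on_failure,
    select_best_cluster,
)

from oracles import covered_query_bases, exhaustive_clusters

P = ChainParams(kmer_size=16, max_shift=0.2, error_rate=0.15)


def _pairs(clusters, qpos, rpos):
    return [
        list(zip(qpos[c.left_idx : c.right_idx + 1],
                 rpos[c.left_idx : c.right_idx + 1]))
        for c in clusters
    ]


def test_zero_drift_single_cluster():
    cl = cluster_matches([0, 20, 40], [0, 20, 40], P)
    assert len(cl) == 1
    assert cl[0].hit_count == 3
    assert (cl[0].q_lo, cl[0].q_hi) == (0, 56)


def test_far_outlier_splits():
    """|dq - dr| = 440 vastly exceeds 0.2 * 460: the outlier is its own run."""
    qpos, rpos = [0, 20, 40, 60], [0, 20, 40, 500]
    cl = cluster_matches(qpos, rpos, P)
    assert _pairs(cl, np.array(qpos), np.array(rpos)) == [
        [(0, 0), (20, 20), (40, 40)],
        [(60, 500)],
    ]


def test_non_monotone_reference_splits():
    cl = cluster_matches([0, 100], [100, 0], P)
    assert len(cl) == 2
    assert all(c.hit_count == 1 for c in cl)


def test_empty_input():
    assert cluster_matches([], [], P) == []


def test_oracle_equivalence_random_arrays(rng):
    """Greedy runs equal the exhaustive adjacent-consistency partition."""
    for _ in range(1000):
        n = int(rng.integers(1, 13))
        qpos = np.sort(rng.integers(0, 100, size=n))
        rpos = rng.integers(0, 100, size=n)
        order = np.lexsort((rpos, qpos))
        qpos, rpos = qpos[order], rpos[order]
        clusters = cluster_matches(qpos, rpos, P)
        expected = exhaustive_clusters(list(zip(qpos, rpos)), P.max_shift)
        assert _pairs(clusters, qpos, rpos) == [
            [(int(q), int(r)) for q, r in run] for run in expected
        ]
        for c, run in zip(clusters, expected):
            assert c.matched_bp == covered_query_bases(run, P.kmer_size)
            assert c.hit_count == len(run)


@settings(derandomize=True, max_examples=200)
@given(
    st.lists(
        st.tuples(st.integers(0, 500), st.integers(0, 500)),
        min_size=1,
        max_size=30,
    )
)
def test_partition_invariants(pairs):
    """Clusters partition V; within a run both coordinates are monotone
    and every adjacent pair satisfies the drift bound."""
    pairs = sorted(set(pairs))
    qpos = np.array([p[0] for p in pairs])
    rpos = np.array([p[1] for p in pairs])
    clusters = cluster_matches(qpos, rpos, P)
    covered = []
    for c in clusters:
        covered.extend(range(c.left_idx, c.right_idx + 1))
        qs = qpos[c.left_idx : c.right_idx + 1]
        rs = rpos[c.left_idx : c.right_idx + 1]
        dq, dr = np.diff(qs), np.diff(rs)
        assert (dq >= 0).all() and (dr >= 0).all()
        assert (np.abs(dq - dr) <= P.max_shift * np.maximum(dq, dr)).all()
        assert c.matched_bp <= (c.q_hi - c.q_lo)
    assert covered == list(range(len(pairs)))


def test_recluster_reversed_order_separates_interleaved_chains():
    """Two chains interleaved under the qpos sort separate under rpos sort."""
    chain1 = [(i * 20, 1000 + i * 20) for i in range(5)]
    chain2 = [(i * 20 + 10, i * 20 + 10) for i in range(5)]
    pairs = sorted(chain1 + chain2)
    qpos = np.array([p[0] for p in pairs])
    rpos = np.array([p[1] for p in pairs])
    first = cluster_matches(qpos, rpos, P)
    assert max(c.hit_count for c in first) < 5
    second = recluster_on_failure(qpos, rpos, P)
    assert max(c.hit_count for c in second) == 5


def test_select_best_cluster_tie_breaks():
    from hisea.clustering import Cluster

    def mk(bp, hits, q_lo):
        return Cluster(0, 0, bp, hits, q_lo, q_lo + 50, 0, 50)

    assert select_best_cluster([mk(48, 3, 0), mk(32, 9, 5)]).matched_bp == 48
    assert select_best_cluster([mk(48, 3, 0), mk(48, 5, 5)]).hit_count == 5
    assert select_best_cluster([mk(48, 3, 7), mk(48, 3, 2)]).q_lo == 2
    assert select_best_cluster([]) is None


def test_binomial_threshold_printed_value():
    """L=5000, e=0.15, k=16: p ~ 0.005517, floor ~ 11.9 (12 hits needed)."""
    p = (1 - 0.15) ** 32
    assert p == pytest.approx(0.0055132, abs=5e-7)
    thr = binomial_threshold(5000, 0.15, 16)
    assert thr == pytest.approx(11.86, abs=0.05)
    assert math.ceil(thr) == 12


@pytest.mark.parametrize("L", [100, 1000, 5000, 20000])
@pytest.mark.parametrize("e", [0.05, 0.10, 0.15, 0.20])
@pytest.mark.parametrize("k", [12, 16])
def test_binomial_threshold_closed_form_grid(L, e, k):
    """Matches independent arithmetic to 12 significant digits, and the
    mean/std of scipy's binomial distribution."""
    p = math.pow(1.0 - e, 2 * k)
    expected = L * p - 3.0 * math.sqrt(L * p * (1.0 - p))
    got = binomial_threshold(L, e, k)
    assert got == pytest.approx(expected, rel=1e-12)
    mean, var = stats.binom.stats(L, p)
    assert got == pytest.approx(float(mean) - 3.0 * math.sqrt(float(var)),
                                rel=1e-9)


def test_binomial_threshold_limits_and_monotonicity():
    assert binomial_threshold(5000, 0.0, 16) == 5000  # p=1, sigma=0
    # tiny L*p: the floor goes non-positive, nothing is eliminated
    assert binomial_threshold(100, 0.20, 16) <= 0
    es = [0.05, 0.10, 0.15, 0.20]
    thr_e = [binomial_threshold(20000, e, 16) for e in es]
    assert all(a > b for a, b in zip(thr_e, thr_e[1:]))  # decreasing in e
    Ls = [1000, 5000, 20000, 100000]
    thr_L = [binomial_threshold(L, 0.15, 16) for L in Ls]
    assert all(a < b for a, b in zip(thr_L, thr_L[1:]))  # increasing in L


def test_binomial_filter_decisions():
    assert binomial_filter(30, 5000, P)        # 30 >= 11.9
    assert not binomial_filter(5, 5000, P)     # 5 < 11.9
    assert binomial_filter(1, 100, ChainParams(error_rate=0.2))  # floor <= 0


def test_alignment_length_reduces_to_projected_form():
    """Query-left/reference-right configuration: L = r_hi + qsize - q_hi."""
    # r starts at its 0 end (r_lo=0), query ends at its size (q_hi near qsize)
    L = alignment_length(q_lo=2000, q_hi=5984, r_lo=0, r_hi=3984,
                         query_size=6000, ref_size=8000)
    assert L == 3984 + (6000 - 5984)  # r_hi + (qsize - q_hi), r_lo = 0
    # identical full-length reads
    assert alignment_length(0, 5000, 0, 5000, 5000, 5000) == 5000
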