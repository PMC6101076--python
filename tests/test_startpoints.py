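import math

import numpy as np
import pytest
from scipy.special import gammaincc

from motifem.scoring import TargetRow, build_letter_matrix
from motifem.seqio import SequenceDataset, encode
from motifem.startpoints import (
    CandidateStart,
    MotifModel,
    SearchConfig,
    SequenceMax,
    StartHeap,
    candidate_pvalue,
    merge_local_maxima,
    nsites_grid,
    rank_candidates,
    search_starting_points,
    select_sequence_maxima,
    sites_to_model,
    weighted_llr,
)
from motifem.synth import PlantSpec, generate_dataset


def _rows(vectors, strands=None, ks=None):
    n = len(vectors)
    strands = strands or ["+"] * n
    ks = ks if ks is not None else list(range(n))
    return [TargetRow(k, s, np.zeros(8, dtype=np.uint8))
            for k, s in zip(ks, strands)]


class TestSequenceMaxima:
    def test_argmax_row(self):
        scores = [np.array([0.1, 0.9, 0.5])]
        out = select_sequence_maxima(scores, _rows(scores), 1)
        assert out[0] == SequenceMax(0, 1, "+", 0.9)

    def test_tie_lowest_position(self):
        scores = [np.array([0.7, 0.7])]
        out = select_sequence_maxima(scores, _rows(scores), 1)
        assert out[0].maxk == 0

    def test_revcomp_takes_better_strand(self):
        scores = [np.array([0.5, 0.2]), np.array([0.1, 0.7])]
        rows = _rows(scores, strands=["+", "-"], ks=[0, 0])
        out = select_sequence_maxima(scores, rows, 1)
        assert out[0].strand == "-"
        assert out[0].score == 0.7

    def test_empty_row_errors(self):
        with pytest.raises(ValueError):
            select_sequence_maxima([np.array([])], _rows([[]]), 1)


class TestMergeLocalMaxima:
    def test_max_of_maxima(self):
        locals_ = [SequenceMax(0, 3, "+", 2.1, local=True),
                   SequenceMax(0, 7, "+", 3.0, local=True)]
        merged = merge_local_maxima(locals_)
        assert merged == [SequenceMax(0, 7, "+", 3.0)]

    def test_single_worker_identity(self):
        locals_ = [SequenceMax(0, 2, "+", 1.5, local=True)]
        assert merge_local_maxima(locals_) == [SequenceMax(0, 2, "+", 1.5)]

    def test_merge_order_invariant(self, rng):
        locals_ = [SequenceMax(k, int(rng.integers(10)), "+",
                               float(rng.normal()), local=True)
                   for k in range(3) for _ in range(4)]
        a = merge_local_maxima(locals_)
        b = merge_local_maxima(list(reversed(locals_)))
        assert a == b


class TestRanking:
    def test_sort_order(self):
        maxima = [SequenceMax(0, 0, "+", 3.0), SequenceMax(1, 0, "+", 1.0),
                  SequenceMax(2, 0, "+", 2.0)]
        [(ns, sites)] = rank_candidates(maxima, "oops")
        assert ns == 3
        assert [m.k for m in sites] == [0, 2, 1]

    def test_oops_single_set(self):
        maxima = [SequenceMax(k, 0, "+", float(k)) for k in range(5)]
        out = rank_candidates(maxima, "oops")
        assert len(out) == 1 and out[0][0] == 5

    def test_zoops_explicit_grid_prefixes(self):
        maxima = [SequenceMax(k, 0, "+", float(-k)) for k in range(10)]
        out = rank_candidates(maxima, "zoops", grid=[2, 4, 8, 10])
        assert [ns for ns, _ in out] == [2, 4, 8, 10]
        for ns, sites in out:
            assert len(sites) == ns
            assert [m.k for m in sites] == list(range(ns))

    def test_default_grid_doubles_to_n(self):
        assert nsites_grid(10) == [2, 3, 5, 10]
        assert nsites_grid(100)[-1] == 100
        assert nsites_grid(2) == [2]

    def test_too_few_sequences(self):
        with pytest.raises(ValueError):
            rank_candidates([SequenceMax(0, 0, "+", 1.0)], "oops")


class TestSitesToModel:
    def test_unanimous_counts(self):
        m = sites_to_model(["AA", "AA"], np.full(4, 0.25), pseudocount=0.0)
        assert m.theta[0, 1] == 1.0 and m.theta[0, 2] == 1.0
        assert np.allclose(m.theta.sum(axis=0), 1.0)

    def test_observed_halves(self):
        m = sites_to_model(["AC", "GT"], np.full(4, 0.25), pseudocount=0.0)
        assert m.theta[0, 1] == 0.5 and m.theta[2, 1] == 0.5
        assert m.theta[1, 2] == 0.5 and m.theta[3, 2] == 0.5

    def test_pseudocount_formula(self):
        m = sites_to_model(["A"], np.full(4, 0.25), pseudocount=1.0)
        assert m.theta[0, 1] == pytest.approx((1 + 0.25) / 2)

    def test_width_mismatch(self):
        with pytest.raises(ValueError):
            sites_to_model(["AA", "AAA"], np.full(4, 0.25))

    def test_column_zero_is_background(self):
        bg = np.array([0.4, 0.3, 0.2, 0.1])
        m = sites_to_model(["ACG"], bg, pseudocount=0.5)
        assert m.theta[:, 0] == pytest.approx(bg)


class TestWeightedLLR:
    def test_unanimous_closed_form(self):
        bg = np.full(4, 0.25)
        m = sites_to_model(["AA", "AA"], bg, pseudocount=0.0)
        # 2 sites x 2 columns x log2(1/0.25) = 8 bits
        assert weighted_llr(m, ["AA", "AA"], bg) == pytest.approx(8.0)

    def test_background_model_scores_zero(self):
        bg = np.full(4, 0.25)
        theta = np.tile(bg[:, None], (1, 4))
        m = MotifModel(theta, 3)
        assert weighted_llr(m, ["ACG", "TTT"], bg) == pytest.approx(0.0)

    def test_matches_double_loop_oracle(self, rng):
        bg = np.array([0.3, 0.25, 0.25, 0.2])
        sites = ["ACGTT", "ACGTA", "TCGTA"]
        m = sites_to_model(sites, bg, pseudocount=0.3)
        expected = sum(
            math.log2(m.theta[encode(s)[p], p + 1] / bg[encode(s)[p]])
            for s in sites for p in range(5)
        )
        assert weighted_llr(m, sites, bg) == pytest.approx(expected)


class TestPvalue:
    def test_null_value(self):
        assert candidate_pvalue(0.0, 5, 4) == 1.0

    def test_monotone_decreasing(self):
        ps = [candidate_pvalue(llr, 5, 4) for llr in (1, 5, 10, 20, 50)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)

    def test_matches_chi_square_tail(self):
        # regularized upper incomplete gamma is the chi-square survival
        x = 2 * math.log(2) * 20.0
        expected = gammaincc((3 * 4) / 2, x / 2)
        assert candidate_pvalue(20.0, 5, 4) == pytest.approx(expected,
                                                             rel=1e-12)


class TestStartHeap:
    def _cand(self, i, j, llr, W=4, ns=3):
        theta = np.tile(np.full(4, 0.25)[:, None], (1, W + 1))
        return CandidateStart((i, j, W, "+"), ns, MotifModel(theta, W),
                              llr, 0.5)

    def test_capacity_one_keeps_best(self):
        heap = StartHeap(capacity=1)
        for i, llr in enumerate([1.0, 5.0, 3.0]):
            heap.offer(self._cand(i, 0, llr))
        [c] = heap.candidates()
        assert c.llr == 5.0

    def test_never_exceeds_capacity_and_dedups(self):
        heap = StartHeap(capacity=3)
        for i in range(10):
            heap.offer(self._cand(i, 0, float(i)))
        assert len(heap) == 3
        assert not heap.offer(self._cand(9, 0, 9.0))  # duplicate seed
        assert [c.llr for c in heap.candidates()] == [9.0, 8.0, 7.0]

    def test_insertion_order_invariant(self, rng):
        cands = [self._cand(i, j, float(rng.normal()))
                 for i in range(5) for j in range(4)]
        h1, h2 = StartHeap(4), StartHeap(4)
        for c in cands:
            h1.offer(c)
        for c in reversed(cands):
            h2.offer(c)
        key = lambda c: (c.seed, c.llr)
        assert [key(c) for c in h1.candidates()] == \
            [key(c) for c in h2.candidates()]


class TestSearch:
    def test_planted_identical_sites_top_seed(self):
        ds, truth = generate_dataset(PlantSpec(
            n=10, L=50, W=8, consensus="ACGTACGT", corruption=0.0, seed=11))
        res = search_starting_points(ds, 8, SearchConfig(model="oops"))
        top = res.top()
        i, j, W, strand = top.seed
        assert (i, j, "+") in [(t[0], t[1], t[2]) for t in truth]
        assert ds.sequences[i][j:j + 8] == "ACGTACGT"

    def test_heap_capacity_one(self, make_dataset):
        ds = make_dataset(n=3, lmin=15, lmax=20)
        res = search_starting_points(
            ds, 5, SearchConfig(model="oops", heap_capacity=1))
        assert len(res.heap) == 1

    def test_deterministic_reruns(self, make_dataset):
        ds = make_dataset(n=4, lmin=15, lmax=25, seed=5)
        key = lambda r: [(c.seed, c.nsites, c.llr, tuple(c.sites))
                         for c in r.heap.candidates()]
        a = search_starting_points(ds, 5, SearchConfig(model="zoops"))
        b = search_starting_points(ds, 5, SearchConfig(model="zoops"))
        assert key(a) == key(b)

    def test_short_sequences_skipped_as_seed(self):
        ds = SequenceDataset(["ACGTACGTACGT", "ACG", "TACGTACGTACG"])
        res = search_starting_points(ds, 6, SearchConfig(model="oops"))
        assert res.counters["seeds_evaluated"] == 2 * (12 - 6 + 1)

    def test_width_larger_than_all_errors(self, make_dataset):
        ds = make_dataset(n=3, lmin=10, lmax=12)
        with pytest.raises(ValueError):
            search_starting_points(ds, 50, SearchConfig())

    def test_candidate_invariants(self, make_dataset):
        ds = make_dataset(n=5, lmin=15, lmax=25, revcomp=True)
        res = search_starting_points(ds, 6, SearchConfig(model="zoops"))
        for c in res.heap.candidates():
            assert c.nsites >= 2
            assert np.isfinite(c.llr)
            assert 0 < c.pvalue <= 1
            assert np.allclose(c.model.theta.sum(axis=0), 1.0, atol=1e-12)
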