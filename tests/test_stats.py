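"""Unit and property tests for the statistical kernel."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsrscan import (
    BaseDepths,
    BsrScanError,
    EnrichmentParams,
    UnigeneEnrichment,
    ZeroDepthError,
    base_frequencies,
    bh_fdr,
    classify_candidate,
    ed_power,
    euclidean_distance,
    hypergeom_tail,
)
from bsrscan.stats import TINY_P, hypergeom_tail_many, screen_significant

depth_vectors = st.tuples(*(st.integers(0, 200),) * 4).filter(lambda d: sum(d) > 0)


class TestBaseFrequencies:
    @pytest.mark.parametrize(
        "depths, expected",
        [
            ((30, 10, 0, 0), (0.75, 0.25, 0.0, 0.0)),
            ((7, 0, 0, 0), (1.0, 0.0, 0.0, 0.0)),
            ((1, 1, 1, 1), (0.25, 0.25, 0.25, 0.25)),
        ],
    )
    def test_direct_ratios(self, depths, expected):
        f = base_frequencies(BaseDepths(*depths))
        assert np.allclose(f.as_array(), expected)

    def test_zero_depth_is_an_error(self):
        with pytest.raises(ZeroDepthError):
            base_frequencies(BaseDepths(0, 0, 0, 0))

    @settings(derandomize=True, max_examples=200)
    @given(depth_vectors)
    def test_frequencies_sum_to_one(self, d):
        f = base_frequencies(BaseDepths(*d)).as_array()
        assert abs(f.sum() - 1.0) < 1e-12
        assert ((0 <= f) & (f <= 1)).all()


class TestEuclideanDistance:
    def test_identical_vectors_give_zero(self):
        f = base_frequencies(BaseDepths(3, 5, 7, 11))
        assert euclidean_distance(f, f) == 0.0

    def test_opposite_fixed_alleles_give_sqrt2(self):
        assert euclidean_distance((1, 0, 0, 0), (0, 1, 0, 0)) == pytest.approx(
            math.sqrt(2), abs=1e-12
        )

    def test_hand_evaluated_case(self):
        # sqrt(2 * 0.5^2) = sqrt(0.5)
        ed = euclidean_distance((0.75, 0.25, 0, 0), (0.25, 0.75, 0, 0))
        assert ed == pytest.approx(math.sqrt(0.5), abs=1e-12)

    @settings(derandomize=True, max_examples=300)
    @given(depth_vectors, depth_vectors)
    def test_symmetry_and_bounds(self, d1, d2):
        f1 = base_frequencies(BaseDepths(*d1))
        f2 = base_frequencies(BaseDepths(*d2))
        ed = euclidean_distance(f1, f2)
        assert ed == euclidean_distance(f2, f1)
        assert 0.0 <= ed <= math.sqrt(2) + 1e-12
        if np.allclose(f1.as_array(), f2.as_array(), atol=1e-12):
            assert ed < 1e-10


class TestEdPower:
    @pytest.mark.parametrize(
        "ed, k, expected",
        [(0.0, 5, 0.0), (1.0, 5, 1.0), (math.sqrt(0.5), 5, 2 ** (-5 / 2))],
    )
    def test_examples(self, ed, k, expected):
        assert ed_power(ed, k) == pytest.approx(expected, abs=1e-9)

    def test_invalid_power(self):
        with pytest.raises(BsrScanError):
            ed_power(0.5, k=0)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.floats(0, 1.414, allow_nan=False),
        st.floats(0, 1.414, allow_nan=False),
        st.integers(1, 9),
    )
    def test_ranking_preserved(self, a, b, k):
        if a > b:
            assert ed_power(a, k) > ed_power(b, k)


class TestClassifyCandidate:
    @pytest.mark.parametrize(
        "ed, expected",
        [(0.74, True), (math.sqrt(2), True), (0.0, False), (0.7399999, False)],
    )
    def test_inclusive_threshold(self, ed, expected):
        assert classify_candidate(ed, threshold=0.74) is expected

    def test_bad_threshold(self):
        with pytest.raises(BsrScanError):
            classify_candidate(0.5, threshold=0.0)


class TestHypergeomTail:
    def test_enumerated_example(self):
        # P(both of a 2-locus unigene land among the 5 candidates of 10 loci)
        # = C(5,2)/C(10,2) = 10/45
        p = hypergeom_tail(EnrichmentParams(10, 5), 2, 2)
        assert p == pytest.approx(10 / 45, abs=1e-12)

    def test_zero_candidates_is_certain(self):
        for m, k, n in [(10, 3, 4), (50, 0, 10), (5, 5, 5)]:
            assert hypergeom_tail(EnrichmentParams(m, k), n, 0) == 1.0

    def test_all_loci_associated_is_certain(self):
        for y in range(0, 5):
            assert hypergeom_tail(EnrichmentParams(12, 12), 4, min(y, 4)) == 1.0

    def test_monotone_non_increasing_in_y(self):
        params = EnrichmentParams(40, 11)
        ps = [hypergeom_tail(params, 8, y) for y in range(9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_count_ordering(self):
        with pytest.raises(BsrScanError):
            hypergeom_tail(EnrichmentParams(10, 5), 3, 4)  # y > N
        with pytest.raises(BsrScanError):
            hypergeom_tail(EnrichmentParams(10, 5), 11, 2)  # N > M

    def test_exact_and_logspace_regimes_agree(self):
        # straddle the switchover population size with identical proportions
        for m, k, n, y in [(999, 300, 12, 6), (1000, 300, 12, 6)]:
            exact = hypergeom_tail(EnrichmentParams(m, k), n, y)
            from scipy.stats import hypergeom

            assert exact == pytest.approx(hypergeom.sf(y - 1, m, k, n), rel=1e-10)

    def test_impossible_tail_reports_tiny_not_zero(self):
        # y exceeds the candidate total: the tail is empty but never 0
        p = hypergeom_tail(EnrichmentParams(20, 2), 5, 3)
        assert p == TINY_P

    def test_vectorized_matches_scalar(self):
        params = EnrichmentParams(200, 17)
        n = np.array([1, 5, 9, 20])
        y = np.array([0, 2, 1, 6])
        p, under = hypergeom_tail_many(params, n, y)
        for i in range(len(n)):
            assert p[i] == pytest.approx(
                hypergeom_tail(params, int(n[i]), int(y[i])), abs=1e-14
            )
        assert not under.any()


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0], [1.0, 1.0]),
            ([0.1, 0.1], [0.1, 0.1]),
        ],
    )
    def test_hand_worked_examples(self, p, expected):
        assert np.allclose(bh_fdr(p), expected, atol=1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(BsrScanError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(BsrScanError):
            bh_fdr([-0.1])

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 200))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.max(np.abs(bh_fdr(p) - ref)) < 1e-12

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=64)
        perm = rng.permutation(64)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), atol=1e-15)


class TestScreenSignificant:
    def _rec(self, uid, fdr):
        return UnigeneEnrichment(uid, 5, 1, fdr / 2, fdr, False)

    def test_strict_cutoff(self):
        recs = [self._rec("a", 0.005), self._rec("b", 0.01), self._rec("c", 0.2)]
        hits = screen_significant(recs, fdr_cutoff=0.01)
        assert [h.unigene_id for h in hits] == ["a"]
        assert all(h.significant for h in hits)

    def test_empty_and_all_null(self):
        assert screen_significant([], 0.01) == []
        recs = [self._rec(u, 1.0) for u in "abc"]
        assert screen_significant(recs, 0.01) == []

    def test_sorted_by_fdr_then_id(self):
        recs = [self._rec("b", 0.003), self._rec("a", 0.003), self._rec("c", 0.001)]
        hits = screen_significant(recs, 0.01)
        assert [h.unigene_id for h in hits] == ["c", "a", "b"]
        ids = {r.unigene_id for r in recs}
        assert {h.unigene_id for h in hits} <= ids
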