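import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from csca import (
    DomainError,
    EvidenceSet,
    bh_fdr,
    bonferroni_adjust,
    hypergeom_upper_tail,
    mc_overlap_null,
    multi_list_scan,
    ora,
    overlap_test,
)
from csca.overlap_stats import empirical_upper_tail


def enumerated_upper_tail(N, K, n, k):
    """Independent oracle: enumerate all C(N, n) equally likely draws from
    a universe whose first K items are marked and count those with >= k
    marked items."""
    hits = sum(1 for draw in itertools.combinations(range(N), n)
               if sum(1 for x in draw if x < K) >= k)
    return hits / math.comb(N, n)


class TestUpperTail:
    def test_all_marked_all_drawn_small_case(self):
        # one draw out of C(10,5)=252 contains all five marked genes
        assert hypergeom_upper_tail(10, 5, 5, 5) == pytest.approx(1 / 252)

    def test_zero_overlap_has_probability_one(self):
        assert hypergeom_upper_tail(1000, 50, 100, 0) == 1.0

    @pytest.mark.parametrize("N, K, n", [(8, 3, 4), (10, 5, 5), (12, 7, 6),
                                         (9, 2, 8), (11, 11, 3)])
    def test_matches_enumeration_oracle(self, N, K, n):
        for k in range(min(K, n) + 1):
            assert hypergeom_upper_tail(N, K, n, k) == \
                pytest.approx(enumerated_upper_tail(N, K, n, k), abs=1e-12)

    @pytest.mark.parametrize("args, fragment", [
        ((1000, 0, 10, 0), "marked_k"),
        ((1000, 2000, 10, 5), "marked_k"),
        ((1000, 10, 2000, 5), "draw_n"),
        ((1000, 10, 10, 11), "overlap_k"),
        ((0, 1, 1, 0), "universe_n"),
    ])
    def test_domain_errors_name_the_violated_inequality(self, args, fragment):
        with pytest.raises(DomainError, match=fragment):
            hypergeom_upper_tail(*args)

    def test_stable_for_large_universe(self):
        p = hypergeom_upper_tail(10**6, 5000, 2000, 50)
        assert 0.0 < p < 1.0 and np.isfinite(p)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(data=st.data())
    def test_marked_and_drawn_roles_exchangeable(self, data):
        N = data.draw(st.integers(2, 200), label="N")
        K = data.draw(st.integers(1, N), label="K")
        n = data.draw(st.integers(1, N), label="n")
        k = data.draw(st.integers(0, min(K, n)), label="k")
        assert hypergeom_upper_tail(N, K, n, k) == \
            pytest.approx(hypergeom_upper_tail(N, n, K, k), rel=1e-10)

    @pytest.mark.parametrize("N, K, n", [(50, 10, 20), (200, 37, 99)])
    def test_pmf_normalizes_and_tail_non_increasing(self, N, K, n):
        support = range(max(0, n + K - N), min(K, n) + 1)
        total = sum(stats.hypergeom.pmf(k, N, K, n) for k in support)
        assert total == pytest.approx(1.0, abs=1e-10)
        tails = [hypergeom_upper_tail(N, K, n, k) for k in range(min(K, n) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))


class TestOverlapTest:
    def test_planted_88_of_1157_in_1003(self):
        query = [f"Q{i}" for i in range(1157)]
        target = query[:88] + [f"T{i}" for i in range(915)]
        r = overlap_test(query, target, 18700)
        assert r.test.overlap_k == 88
        assert r.expected == pytest.approx(1157 * 1003 / 18700, rel=1e-12)
        assert r.expected == pytest.approx(62.05, abs=0.01)
        assert r.p_upper == pytest.approx(0.0005, abs=0.0001)

    def test_disjoint_sets(self):
        r = overlap_test({"A", "B"}, {"C", "D"}, 100)
        assert (r.test.overlap_k, r.fold_enrichment, r.p_upper) == (0, 0.0, 1.0)

    def test_identical_sets_reproduce_enumerated_case(self):
        genes = {f"G{i}" for i in range(5)}
        r = overlap_test(genes, genes, 10)
        assert r.p_upper == pytest.approx(1 / 252)

    def test_restriction_overrides_nominal_universe_with_warning(self):
        universe = [f"G{i}" for i in range(20)]
        with pytest.warns(UserWarning, match="overriding"):
            r = overlap_test(universe[:8], universe[4:12], 50,
                             restrict_to_universe=universe)
        assert r.test.universe_n == 20
        assert r.test.overlap_k == 4

    def test_query_larger_than_universe_rejected(self):
        with pytest.raises(DomainError, match="exceeds"):
            overlap_test({f"G{i}" for i in range(30)}, {"G1"}, 10)


class TestMonteCarloNull:
    def test_single_rep_count_in_range(self):
        (c,) = mc_overlap_null(10, 5, 5, reps=1, seed=7)
        assert 0 <= c <= 5

    def test_empirical_tail_within_three_se_of_enumeration(self):
        reps = 20000
        counts = mc_overlap_null(10, 5, 5, reps=reps, seed=7)
        exact = 1 / 252
        emp = empirical_upper_tail(counts, 5)
        se = math.sqrt(exact * (1 - exact) / reps)
        assert abs(emp - exact) <= 3 * se

    def test_deterministic_under_fixed_seed(self):
        a = mc_overlap_null(40, 10, 12, reps=500, seed=3)
        b = mc_overlap_null(40, 10, 12, reps=500, seed=3)
        assert np.array_equal(a, b)


class TestCorrections:
    def test_bonferroni_thirteen_lists(self):
        assert bonferroni_adjust(0.00054, 13) == pytest.approx(0.00702)

    def test_bonferroni_caps_at_one_and_keeps_zero(self):
        assert bonferroni_adjust(0.5, 3) == 1.0
        assert bonferroni_adjust(0.0, 100) == 0.0

    def test_bh_step_up_hand_derived(self):
        # 0.01*3/1, 0.02*3/2, 0.03*3/3, then cummin from the largest
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_bh_single_p_unchanged(self):
        assert bh_fdr([0.2]) == [0.2]

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(DomainError):
            bh_fdr([0.1, 1.5])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                       max_size=20))
    def test_bh_never_shrinks_and_caps_at_one(self, ps):
        qs = bh_fdr(ps)
        assert all(q >= p - 1e-12 for p, q in zip(ps, qs))
        assert all(0 <= q <= 1 for q in qs)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(p=st.floats(0, 1, allow_nan=False))
    def test_bh_and_bonferroni_agree_for_single_test(self, p):
        assert bh_fdr([p])[0] == pytest.approx(bonferroni_adjust(p, 1))


def make_sets(universe, sizes, planted_query=None, planted_k=0):
    sets = []
    pos = 0
    for i, size in enumerate(sizes):
        if i == 0 and planted_query is not None:
            genes = set(planted_query[:planted_k]) | \
                set(universe[pos:pos + size - planted_k])
        else:
            genes = set(universe[pos:pos + size])
        pos += size
        sets.append(EvidenceSet(name=f"s{i}", category="scan",
                                genes=frozenset(genes), weight=0.0))
    return sets


class TestMultiListScan:
    def test_only_planted_list_survives_bonferroni(self):
        universe = [f"U{i}" for i in range(2000)]
        query = [f"Q{i}" for i in range(100)]
        targets = make_sets(universe, [50] * 13, planted_query=query,
                            planted_k=30)
        results = multi_list_scan(query, targets, 2000)
        flagged = [r.name for r in results if r.p_adjusted < 0.05]
        assert flagged == ["s0"]
        assert all(r.p_adjusted == min(1.0, 13 * r.p_upper) for r in results)

    def test_single_target_adjustment_is_identity(self):
        universe = [f"U{i}" for i in range(100)]
        targets = make_sets(universe, [10])
        (r,) = multi_list_scan(universe[:20], targets, 100)
        assert r.p_adjusted == r.p_upper

    def test_bh_correction_supported(self):
        universe = [f"U{i}" for i in range(500)]
        targets = make_sets(universe, [20, 20, 20])
        results = multi_list_scan(universe[:50], targets, 500, correction="bh")
        assert bh_fdr([r.p_upper for r in results]) == \
            [r.p_adjusted for r in results]

    def test_no_targets_rejected(self):
        with pytest.raises(DomainError):
            multi_list_scan({"A"}, [], 100)


class TestOra:
    def test_fisher_equals_hypergeometric_tail(self):
        universe = [f"U{i}" for i in range(300)]
        query = universe[:40]
        annotations = make_sets(universe, [25, 30, 10])
        table = ora(query, annotations, 300)
        for _, row in table.iterrows():
            tail = hypergeom_upper_tail(300, int(row.marked_k),
                                        int(row.draw_n), int(row.overlap_k)) \
                if row.overlap_k else 1.0
            assert row.p_fisher_one_sided == pytest.approx(tail, abs=1e-12)

    def test_fold_enrichment_values(self):
        universe = [f"U{i}" for i in range(1000)]
        query = universe[:100]
        # K=50 with k=20 inside the query
        annotation = EvidenceSet(
            name="a", category="annotation", weight=0.0,
            genes=frozenset(universe[80:100]) | frozenset(universe[100:130]))
        table = ora(query, [annotation], 1000)
        assert table.loc[0, "overlap_k"] == 20
        assert table.loc[0, "fold_enrichment"] == pytest.approx(4.0)

    def test_zero_overlap_has_zero_fold_enrichment(self):
        universe = [f"U{i}" for i in range(100)]
        table = ora(universe[:10], make_sets(universe[50:], [10]), 100)
        assert table.loc[0, "fold_enrichment"] == 0.0
        assert table.loc[0, "p_fisher_one_sided"] == pytest.approx(1.0)

    def test_bh_column_and_flag(self):
        universe = [f"U{i}" for i in range(400)]
        query = universe[:50]
        annotations = make_sets(universe, [30, 30],
                                planted_query=query, planted_k=25)
        table = ora(query, annotations, 400)
        assert list(table["q_bh"]) == bh_fdr(list(table["p_fisher_one_sided"]))
        assert bool(table.loc[0, "significant"])
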