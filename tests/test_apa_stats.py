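"""Differential-usage statistics: chi-square, indices, tails, gene-set tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apa3seq import apa_stats
from apa3seq.apa_stats import (
    UsageTable,
    analyze_usage_tables,
    binomial_direction_test,
    chi_square_usage,
    classify_shift,
    compute_pui,
    core_set_intersection,
    geneset_shift_test,
    intronic_shift_test,
    proliferation_index,
    proximal_pui_median,
    rank_sum_test,
    weighted_cs_index,
)
from apa3seq.errors import InputError, UntestableTableError


def chi2_textbook(table):
    """Independent Pearson chi-square: explicit O/E double loop."""
    t = np.asarray(table, dtype=float)
    rows, cols, total = t.sum(axis=1), t.sum(axis=0), t.sum()
    stat = 0.0
    for i in range(t.shape[0]):
        for j in range(t.shape[1]):
            e = rows[i] * cols[j] / total
            stat += (t[i, j] - e) ** 2 / e
    return stat


class TestChiSquare:
    @pytest.mark.parametrize(
        "table,chi2,df",
        [
            ([[50, 50], [50, 50]], 0.0, 1),
            ([[90, 10], [10, 90]], 128.0, 1),
            ([[30, 20], [20, 30]], 4.0, 1),
        ],
    )
    def test_known_tables(self, table, chi2, df):
        stat, d, p = chi_square_usage(table)
        assert stat == pytest.approx(chi2, abs=1e-12)
        assert d == df

    def test_perfect_independence_p_one(self):
        _, _, p = chi_square_usage([[50, 50], [50, 50]])
        assert p == 1.0

    def test_balanced_2x2_pvalue(self):
        _, _, p = chi_square_usage([[30, 20], [20, 30]])
        assert p == pytest.approx(0.0455, abs=2e-4)

    def test_zero_margin_rejected(self):
        with pytest.raises(UntestableTableError):
            chi_square_usage([[0, 0], [10, 20]])
        with pytest.raises(UntestableTableError):
            chi_square_usage([[5, 0], [10, 0]])

    def test_agrees_with_textbook_on_random_tables(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            shape = (rng.integers(2, 5), rng.integers(2, 4))
            table = rng.integers(1, 200, size=shape)
            stat, _, _ = chi_square_usage(table)
            assert abs(stat - chi2_textbook(table)) < 1e-9


class TestWeightedCsIndex:
    @pytest.mark.parametrize(
        "levels,expected",
        [([1, 1], 1.5), ([3, 1], 1.25), ([0, 1], 2.0)],
    )
    def test_examples(self, levels, expected):
        assert weighted_cs_index(levels) == pytest.approx(expected)

    def test_all_zero_undefined(self):
        with pytest.raises(InputError):
            weighted_cs_index([0, 0, 0])

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=8))
    @settings(deadline=None, derandomize=True)
    def test_bounded_by_ordinal_range(self, levels):
        idx = weighted_cs_index(levels)
        assert 1.0 - 1e-9 <= idx <= len(levels) + 1e-9

    def test_uniform_levels_give_midpoint(self):
        for n in (2, 3, 5, 9):
            assert weighted_cs_index([7] * n) == pytest.approx((n + 1) / 2)


class TestClassifyShift:
    def test_directions(self):
        assert classify_shift({"a": 1.8, "b": 1.2}, 1e-5, "a", "b") == "shortened"
        assert classify_shift({"a": 1.2, "b": 1.8}, 1e-5, "a", "b") == "lengthened"
        assert classify_shift({"a": 1.8, "b": 1.2}, 0.01, "a", "b") == "none"
        assert classify_shift({"a": 1.5, "b": 1.5}, 1e-5, "a", "b") == "none"


class TestBinomialTail:
    def test_three_of_three(self):
        assert binomial_direction_test(3, 3).p_binomial == pytest.approx(0.125)

    def test_no_underflow_in_deep_tail(self):
        r = binomial_direction_test(4000, 4096)
        assert r.p_binomial >= 0.0
        assert r.log10_p < -300  # resolved in log space even when p underflows

    def test_half_split_at_least_half(self):
        for n in (10, 100, 668):
            assert binomial_direction_test(n // 2, n).p_binomial >= 0.5

    def test_monotone_decreasing_in_k(self):
        ps = [binomial_direction_test(k, 200).p_binomial for k in range(80, 200, 7)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_invalid_k_rejected(self):
        with pytest.raises(InputError):
            binomial_direction_test(5, 3)


class TestPUI:
    def test_four_one_pseudocount_zero(self):
        assert np.allclose(compute_pui([4, 1], pseudocount=0), [1.0, -1.0])

    def test_equal_levels_zero(self):
        assert np.allclose(compute_pui([6, 6, 6], pseudocount=0), 0.0)

    def test_three_site_example(self):
        pui = compute_pui([8, 2, 2], pseudocount=0)
        assert np.allclose(pui, [4 / 3, -2 / 3, -2 / 3])

    def test_sums_to_zero_for_random_transcripts(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            levels = rng.integers(0, 500, size=rng.integers(2, 6))
            assert abs(compute_pui(levels).sum()) < 1e-9

    def test_single_site_rejected(self):
        with pytest.raises(InputError):
            compute_pui([5])


class TestProximalPuiMedian:
    def test_median_of_proximal_values(self):
        table = {
            "t1": {"a": np.array([-1.0, 1.0])},
            "t2": {"a": np.array([0.0, 0.0])},
            "t3": {"a": np.array([1.0, -1.0])},
        }
        assert proximal_pui_median(table, "a") == 0.0

    def test_constant_proximal(self):
        table = {f"t{i}": {"a": np.array([0.7, -0.7])} for i in range(5)}
        assert proximal_pui_median(table, "a") == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            proximal_pui_median({}, "a")


class TestIntronicShift:
    def test_example_table(self):
        summary = intronic_shift_test([("t1", [10, 40], [90, 60])], to_idx=1, from_idx=0)
        tid, chi2, p, toward = summary.results[0]
        assert chi2 == pytest.approx(24.0)
        assert p < 1e-5
        assert toward  # intronic share 40% in to-condition vs 10%

    def test_identical_proportions_not_significant(self):
        summary = intronic_shift_test([("t1", [20, 20], [80, 80])])
        _, chi2, p, toward = summary.results[0]
        assert chi2 == pytest.approx(0.0) and p == 1.0 and not toward

    def test_direction_tally_binomial(self):
        # 12 of 14 significant transcripts toward intronic: P(X>=12) = 0.0065
        tables = [("s%d" % i, [10, 60], [90, 40]) for i in range(12)]
        tables += [("o%d" % i, [60, 10], [40, 90]) for i in range(2)]
        summary = intronic_shift_test(tables, to_idx=1, from_idx=0)
        assert summary.n_significant == 14
        assert summary.k_toward_intronic == 12
        assert summary.direction_test.p_binomial == pytest.approx(0.0064697265625)

    def test_zero_margin_skipped(self):
        summary = intronic_shift_test([("t1", [0, 0], [10, 20])])
        assert summary.n_tested == 0 and summary.results == []


class TestCoreSet:
    def _r(self, tid, direction):
        return apa_stats.TranscriptAPAResult(tid, 10.0, 1, 1e-5, {}, direction)

    def test_consistent_and_opposing(self):
        a = [self._r("t1", "shortened"), self._r("t2", "lengthened")]
        b = [self._r("t1", "shortened"), self._r("t2", "shortened")]
        consistent, opposing, p = core_set_intersection(a, b)
        assert consistent == ["t1"] and opposing == ["t2"]

    def test_disjoint_significant_sets(self):
        a = [self._r("t1", "shortened")]
        b = [self._r("t2", "shortened")]
        consistent, opposing, p = core_set_intersection(a, b)
        assert consistent == [] and opposing == [] and p is None

    def test_enrichment_tail_small(self):
        # 203 of 216 core transcripts shortened while the single systems run
        # at 83% and 75% shortened: the binomial tail against the larger
        # fraction is far below 1e-4
        shared_s = [self._r(f"t{i}", "shortened") for i in range(203)]
        shared_l = [self._r(f"u{i}", "lengthened") for i in range(13)]
        a = shared_s + shared_l + [self._r(f"x{i}", "lengthened") for i in range(28)]
        b = shared_s + shared_l + [self._r(f"y{i}", "lengthened") for i in range(54)]
        consistent, opposing, p = core_set_intersection(a, b)
        assert len(consistent) == 216 and opposing == []
        assert 203 / len(a) == pytest.approx(0.83, abs=0.01)
        assert 203 / len(b) == pytest.approx(0.75, abs=0.01)
        assert p < 1e-4


class TestExpressionIndices:
    def test_proliferation_index_examples(self):
        import pandas as pd

        expr = pd.DataFrame({"a": [5.0, 10.0, 20.0, 40.0]}, index=list("wxyz"))
        assert proliferation_index(expr, {"y", "z"}, "a") == pytest.approx(1.0)
        assert proliferation_index(expr, {"w", "x", "y", "z"}, "a") == 0.0
        # cell-cycle median 8x the overall median
        expr8 = pd.DataFrame({"a": [1.0, 1.0, 8.0, 8.0, 1.0]}, index=list("vwxyz"))
        assert proliferation_index(expr8, {"x", "y"}, "a") == pytest.approx(3.0)

    def test_missing_gene_set_rejected(self):
        import pandas as pd

        expr = pd.DataFrame({"a": [1.0]}, index=["g"])
        with pytest.raises(InputError):
            proliferation_index(expr, {"absent"}, "a")


class TestRankSum:
    def test_identical_distributions(self):
        assert rank_sum_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_complete_separation_exact(self):
        assert rank_sum_test([-1.0, -1.1, -1.2], [1.0, 1.1, 1.2]) == pytest.approx(0.1)

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(3)
        x = rng.normal(-10, 1, size=50)
        y = rng.normal(0, 1, size=50)
        assert rank_sum_test(x, y) < 1e-10

    def test_geneset_shift_wrapper(self):
        fc = {f"g{i}": v for i, v in enumerate([-1.0, -1.1, -1.2, 1.0, 1.1, 1.2])}
        res = geneset_shift_test(fc, {"g0", "g1", "g2"})
        assert res.p_wilcoxon == pytest.approx(0.1)
        with pytest.raises(InputError):
            geneset_shift_test(fc, set(fc))  # empty background


class TestUsageTableAnalysis:
    def test_direction_and_significance(self):
        tables = [
            UsageTable("shift", ["a", "b"], [[90, 10], [10, 90]]),
            UsageTable("null", ["a", "b"], [[50, 50], [50, 50]]),
        ]
        results, untestable = analyze_usage_tables(tables, from_cond="b", to_cond="a")
        assert untestable == []
        by_id = {r.transcript_id: r for r in results}
        assert by_id["shift"].direction == "shortened"
        assert by_id["shift"].cs_index["a"] == pytest.approx(1.1)
        assert by_id["null"].direction == "none"

    def test_untestable_table_logged_not_raised(self):
        tables = [UsageTable("dead", ["a", "b"], [[0, 0], [10, 20]])]
        results, untestable = analyze_usage_tables(tables, from_cond="b", to_cond="a")
        assert results == [] and untestable == ["dead"]
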