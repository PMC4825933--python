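"""Temporal fold-changes, order statistics, rank tests, contingency tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from archncc import (
    ContingencyTable,
    chi_square_penetrance,
    compare_lists,
    kruskal_wallis,
    mann_whitney_u,
    summarize_list,
    temporal_fold_changes,
)
from archncc.stats import bonferroni


def brute_force_mw_p(x, y):
    """Independent oracle: enumerate assignments, U by pairwise counting."""
    pooled = list(x) + list(y)
    n = len(x)
    mu = n * len(y) / 2.0

    def u_of(group_x, group_y):
        return sum(
            1.0 if a > b else 0.5 if a == b else 0.0
            for a in group_x
            for b in group_y
        )

    u_obs = u_of(x, y)
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        gx = [pooled[i] for i in idx]
        gy = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_of(gx, gy) - mu) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestTemporalFoldChanges:
    def test_direct_ratios_and_zero_rule(self, worked_example):
        matrix, design, _ = worked_example
        # worked-example genes have DP profile (v/2, v, v)
        tf = temporal_fold_changes(matrix, design, universe=["above_min"])
        assert tf.at["above_min", "fc_20_28"] == pytest.approx(2.0)
        assert tf.at["above_min", "fc_28_36"] == pytest.approx(1.0)

    def test_zero_baseline_replaced(self, worked_example):
        matrix, design, _ = worked_example
        patched = matrix.data.copy()
        patched.loc["above_min", "wt_dp_20"] = 0.0
        patched.loc["above_min", "wt_dp_28"] = 5.0
        from archncc import ExpressionMatrix

        tf = temporal_fold_changes(
            ExpressionMatrix(patched), design, universe=["above_min"]
        )
        assert tf.at["above_min", "fc_20_28"] == pytest.approx(500.0)

    def test_constant_gene_is_unchanged(self, worked_example):
        matrix, design, _ = worked_example
        patched = matrix.data.copy()
        patched.loc["above_min", ["wt_dp_20", "wt_dp_28", "wt_dp_36"]] = 7.0
        from archncc import ExpressionMatrix

        tf = temporal_fold_changes(
            ExpressionMatrix(patched), design, universe=["above_min"]
        )
        assert tf.loc["above_min"].tolist() == [1.0, 1.0]


class TestSummarizeList:
    def test_median_and_threshold_count(self):
        s = summarize_list([1.0, 2.0, 4.0])
        assert s.median == 2.0 and s.n == 3
        assert summarize_list([11.0, 9.0, 12.0]).count_over_threshold == 2
        assert summarize_list([10.0, 10.0]).count_over_threshold == 0  # strict >

    def test_quantiles_match_sort_and_interpolate_oracle(self):
        values = list(range(1, 9))  # 1..8

        def interp_quantile(sorted_vals, q):
            pos = q * (len(sorted_vals) - 1)
            lo = math.floor(pos)
            hi = math.ceil(pos)
            frac = pos - lo
            return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac

        s = summarize_list(values)
        for attr, q in (("p5", 0.05), ("q1", 0.25), ("median", 0.5),
                        ("q3", 0.75), ("p95", 0.95)):
            assert getattr(s, attr) == pytest.approx(interp_quantile(values, q))
        assert s.p5 <= s.q1 <= s.median <= s.q3 <= s.p95

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            summarize_list([])


class TestMannWhitney:
    def test_separated_groups_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2 / C(6,3)

    def test_identical_multisets_give_p_one(self):
        _, p = mann_whitney_u([1, 2, 2, 3], [3, 2, 1, 2], mode="exact")
        assert p == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_scipy_on_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(2, 6))
        y = rng.normal(size=rng.integers(2, 6))
        _, p = mann_whitney_u(x, y, mode="exact")
        expected = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(expected.pvalue, abs=1e-12)

    def test_exact_matches_brute_force_with_ties(self):
        x = [1.0, 2.0, 2.0, 5.0]
        y = [2.0, 3.0, 3.0]
        _, p = mann_whitney_u(x, y, mode="exact")
        assert p == pytest.approx(brute_force_mw_p(x, y), abs=1e-12)

    def test_approximate_close_to_exact_at_n8(self):
        x = [1.2, 3.4, 2.2, 5.0]
        y = [0.1, 4.4, 6.1, 2.0]
        _, p_exact = mann_whitney_u(x, y, mode="exact")
        _, p_approx = mann_whitney_u(x, y, mode="approximate")
        assert p_approx == pytest.approx(p_exact, abs=0.15)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        st.lists(st.integers(-5, 5), min_size=2, max_size=5),
        st.lists(st.integers(-5, 5), min_size=2, max_size=5),
    )
    def test_invariance_under_monotone_transform(self, x, y):
        _, p1 = mann_whitney_u(x, y, mode="exact")
        fx = [math.exp(v) for v in x]
        fy = [math.exp(v) for v in y]
        _, p2 = mann_whitney_u(fx, fy, mode="exact")
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKruskalWallis:
    def test_all_observations_equal_gives_zero(self):
        h, p = kruskal_wallis([[3.0, 3.0], [3.0], [3.0, 3.0, 3.0]])
        assert h == 0.0 and p == 1.0

    def test_three_separated_groups_match_rank_formula(self):
        # ranks 1..6, rank sums 3, 7, 11 -> H = 32/7 by direct computation
        h, _ = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(32.0 / 7.0)

    def test_two_group_case_matches_mw_normal_approximation(self):
        x = [1.0, 4.0, 2.5, 7.0, 0.5]
        y = [3.0, 8.0, 9.0, 2.0]
        _, p_kw = kruskal_wallis([x, y])
        _, p_mw = mann_whitney_u(x, y, mode="approximate")
        assert p_kw == pytest.approx(p_mw, abs=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [list(rng.integers(0, 6, size=rng.integers(3, 8)))
                  for _ in range(3)]
        h, p = kruskal_wallis(groups)
        expected = sps.kruskal(*groups)
        assert h == pytest.approx(expected.statistic)
        assert p == pytest.approx(expected.pvalue)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])


class TestBonferroni:
    def test_multiplication_and_cap(self):
        assert bonferroni(0.02, 5) == pytest.approx(0.1)
        assert bonferroni(0.5, 4) == 1.0
        # adjustment of each p does not depend on the others
        ps = [0.2, 0.01, 0.04]
        assert sorted(bonferroni(p, 3) for p in ps) == [
            bonferroni(p, 3) for p in sorted(ps)
        ]


class TestCompareLists:
    @staticmethod
    def _temporal(fcs: dict[str, float]) -> pd.DataFrame:
        return pd.DataFrame(
            {"fc_20_28": pd.Series(fcs), "fc_28_36": pd.Series(fcs)}
        )

    def test_identical_lists_not_flagged(self):
        genes = {f"g{i}": 1.0 + 0.1 * i for i in range(20)}
        temporal = self._temporal(genes)
        lists = {"total": set(genes), "copy_a": set(genes), "copy_b": set(genes)}
        report = compare_lists(temporal, lists, "20_28")
        assert report.flagged() == []
        assert report.n_pairwise == 2

    def test_planted_tenfold_list_is_flagged(self):
        background = {f"g{i}": 1.0 + 0.01 * i for i in range(40)}
        planted = {f"h{i}": 10.0 * (1.0 + 0.01 * i) for i in range(15)}
        temporal = self._temporal({**background, **planted})
        lists = {
            "total": set(background) | set(planted),
            "planted": set(planted),
        }
        report = compare_lists(temporal, lists, "20_28")
        comp = report.lists["planted"]
        assert comp.significant
        assert comp.summary.median > report.total.median
        assert comp.p_adjusted == pytest.approx(
            min(1.0, comp.p_raw * report.n_pairwise)
        )

    def test_short_list_skipped_with_warning(self):
        genes = {f"g{i}": float(i + 1) for i in range(10)}
        temporal = self._temporal(genes)
        lists = {"total": set(genes), "tiny": {"g1"}}
        with pytest.warns(UserWarning, match="tiny"):
            report = compare_lists(temporal, lists, "20_28")
        assert report.lists["tiny"].p_raw is None


class TestChiSquarePenetrance:
    def test_homogeneous_table_gives_zero(self):
        table = ContingencyTable(("a", "b"), (10, 10), (10, 10))
        res = chi_square_penetrance(table)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_closed_form_2x2(self):
        # posterior palatoquadrate truncation: 16/16 single vs 11/27 double mutants
        table = ContingencyTable(("jag1b", "jag1b;barx1"), (16, 11), (0, 16))
        res = chi_square_penetrance(table)
        a, b, c, d = 16, 0, 11, 16
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(closed)
        assert res.p_value < 0.05
        assert res.min_expected == pytest.approx(16 * 16 / 43)  # smallest cell
        assert not res.low_expected_warning  # 5.95 >= 5

    @pytest.mark.parametrize("seed", range(5))
    def test_closed_form_identity_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(1, 40, size=4)
        res = chi_square_penetrance(
            ContingencyTable(("x", "y"), (int(a), int(c)), (int(b), int(d)))
        )
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(float(closed))

    def test_fisher_mode_on_2x2(self):
        table = ContingencyTable(("x", "y"), (16, 11), (0, 16))
        res = chi_square_penetrance(table, mode="fisher")
        assert res.method == "fisher"
        assert 0 < res.p_value < 0.05

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            chi_square_penetrance(
                ContingencyTable(("x", "y", "z"), (0, 5, 3), (0, 4, 2))
            )

    def test_three_by_two_dof(self):
        table = ContingencyTable(("a", "b", "c"), (5, 10, 20), (15, 10, 5))
        res = chi_square_penetrance(table)
        assert res.dof == 2
        assert res.p_value == pytest.approx(
            float(sps.chi2.sf(res.statistic, 2))
        )
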