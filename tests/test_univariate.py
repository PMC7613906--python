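"""Fold changes, group-comparison ladder, exact tests, Bonferroni."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from psymetab.univariate import (
    bonferroni_adjust,
    compare_groups,
    dunn_posthoc,
    dunnett_t3_posthoc,
    fisher_exact,
    fold_changes,
)


class TestFoldChanges:
    def test_identical_groups_give_unit_folds(self, rng):
        vals = pd.DataFrame(
            np.tile(rng.uniform(0.5, 2.0, 6), (12, 1)),
            index=[f"s{i}" for i in range(12)],
            columns=[f"b{i}" for i in range(6)],
        )
        groups = ["Control"] * 6 + ["Case"] * 6
        folds = fold_changes(vals, groups, reference="Control")
        assert np.allclose(folds["fold_Case_vs_Control"], 1.0)

    def test_doubled_case_gives_fold_two(self):
        vals = pd.DataFrame(
            np.vstack([np.ones((5, 3)), 2 * np.ones((5, 3))]),
            index=[f"s{i}" for i in range(10)],
            columns=["a", "b", "c"],
        )
        folds = fold_changes(vals, ["Control"] * 5 + ["Case"] * 5, reference="Control")
        assert np.allclose(folds["fold_Case_vs_Control"], 2.0)

    def test_zero_reference_mean_rejected_naming_bin(self):
        vals = pd.DataFrame(
            {"good": [1, 1, 2, 2], "deadbin": [0, 0, 1, 1]},
            index=["s0", "s1", "s2", "s3"],
        )
        with pytest.raises(ValueError, match="deadbin"):
            fold_changes(vals, ["Control", "Control", "Case", "Case"], reference="Control")

    def test_planted_directions_in_default_cohort(self, default_matrix, default_cohort):
        bm, meta = default_matrix
        _, _, truth = default_cohort
        g = meta.set_index("sample_id")["analysis_group"]
        planted = truth["bins_by_metabolite"]["VGKC_GlyR"]
        folds = fold_changes(bm.values, g, reference="Control")
        col = "fold_VGKC_GlyR_vs_Control"
        assert all(folds.loc[b, col] < 1.0 for b in planted["lipid_ch3"])
        assert all(folds.loc[b, col] > 1.0 for b in planted["glucose"])


class TestCompareGroups:
    def test_identical_groups_yield_unit_pvalues(self):
        vals = np.array([1.0, 2, 3] * 3)
        groups = np.repeat(["a", "b", "c"], 3)
        res = compare_groups(vals, groups, method="anova_tukey")
        assert res.omnibus_stat == pytest.approx(0.0, abs=1e-12)
        assert res.omnibus_p == pytest.approx(1.0)
        assert np.allclose(res.posthoc["p_raw"], 1.0, atol=1e-9)

    def test_separated_tight_groups_tukey_highly_significant(self, rng):
        vals = np.concatenate([rng.normal(m, 0.1, 5) for m in (0.0, 10.0, 20.0)])
        groups = np.repeat(["a", "b", "c"], 5)
        res = compare_groups(vals, groups, method="anova_tukey")
        assert (res.posthoc["p_raw"] < 1e-3).all()

    def test_mann_whitney_exact_p_for_disjoint_ranks(self):
        res = compare_groups(
            np.array([1.0, 2, 3, 4, 5, 6]),
            np.array(["a", "a", "a", "b", "b", "b"]),
            method="mann_whitney",
        )
        assert res.omnibus_p == pytest.approx(0.1, abs=1e-12)  # 2 * 1/C(6,3)

    def test_auto_picks_heteroscedastic_branch(self, rng):
        vals = np.concatenate(
            [rng.normal(0, 0.5, 25), rng.normal(0.3, 0.5, 25), rng.normal(0, 8.0, 25)]
        )
        groups = np.repeat(["a", "b", "c"], 25)
        res = compare_groups(vals, groups, method="auto")
        assert res.method == "welch_bf_dunnettT3"
        assert "brown_forsythe_p" in res.extras

    def test_auto_picks_nonparametric_branch_for_skewed_data(self, rng):
        vals = np.concatenate([rng.exponential(1.0, 30), rng.exponential(3.0, 30)])
        groups = np.repeat(["a", "b"], 30)
        res = compare_groups(vals, groups, method="auto")
        assert res.method == "mann_whitney"

    def test_kruskal_dunn_flags_shifted_group(self, rng):
        vals = np.concatenate(
            [rng.normal(0, 1, 20), rng.normal(0, 1, 20), rng.normal(3, 1, 20)]
        )
        groups = np.repeat(["a", "b", "c"], 20)
        res = compare_groups(vals, groups, method="kruskal_dunn")
        assert res.omnibus_p < 0.001
        ph = res.posthoc.set_index(["group1", "group2"])
        assert ph.loc[("a", "c"), "p_adjusted"] < 0.01
        assert ph.loc[("a", "b"), "p_adjusted"] > 0.05

    def test_degenerate_constant_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compare_groups(np.ones(9), np.repeat(["a", "b", "c"], 3))

    def test_tukey_never_below_unadjusted_pairwise_t(self, rng):
        for _ in range(10):
            arrays = [rng.normal(rng.normal(0, 0.5), 1.0, rng.integers(5, 12)) for _ in range(3)]
            vals = np.concatenate(arrays)
            groups = np.concatenate([[g] * len(a) for g, a in zip("abc", arrays)])
            res = compare_groups(vals, groups, method="anova_tukey")
            for _, row in res.posthoc.iterrows():
                a = arrays["abc".index(row["group1"])]
                b = arrays["abc".index(row["group2"])]
                p_t = stats.ttest_ind(a, b).pvalue
                assert row["p_raw"] >= p_t - 1e-12

    def test_omnibus_type_i_error_calibrated_under_null(self):
        rejections = 0
        n_reps = 1000
        r = np.random.default_rng(123)
        groups = np.repeat(["a", "b", "c"], 10)
        for _ in range(n_reps):
            vals = r.normal(size=30)
            res = compare_groups(vals, groups, method="anova_tukey")
            rejections += res.omnibus_p < 0.05
        rate = rejections / n_reps
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert 0.05 - 2 * se <= rate <= 0.05 + 2 * se


def _fisher_enumeration_p(table):
    """Two-sided Fisher p by exhaustive fixed-margin enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


class TestFisherExact:
    def test_homogeneous_table_p_one(self):
        p, odds, note = fisher_exact([[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)
        assert odds == pytest.approx(1.0)

    def test_perfect_association_exact_probability(self):
        p, odds, note = fisher_exact([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-12)
        assert "Haldane" in note

    def test_episode_type_table_matches_enumeration(self):
        # first-episode vs relapse counts for two patient groups (unknowns dropped)
        table = [[45, 24], [13, 0]]
        p, _, _ = fisher_exact(table)
        assert p == pytest.approx(_fisher_enumeration_p(table), rel=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_for_small_tables(self, seed):
        r = np.random.default_rng(seed)
        while True:
            t = r.integers(0, 7, size=(2, 2))
            if t.sum() <= 12 and t.sum(axis=0).min() > 0 and t.sum(axis=1).min() > 0:
                break
        p, _, _ = fisher_exact(t)
        assert p == pytest.approx(_fisher_enumeration_p(t.tolist()), rel=1e-10)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError, match="margin"):
            fisher_exact([[0, 0], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact([[1.5, 2], [3, 4]])


class TestMannWhitneyOracle:
    def test_exact_p_matches_rank_enumeration(self):
        x = [1.0, 2.0, 3.0]
        y = [4.0, 5.0, 6.0]
        # enumerate all C(6,3)=20 assignments of ranks; count U as extreme
        pooled = np.array(x + y)
        u_obs = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        count = total = 0
        u_stat = 0.0  # observed U for x vs y
        for xi in x:
            u_stat += sum(xi > yi for yi in y)
        for pick in combinations(range(6), 3):
            mask = np.zeros(6, dtype=bool)
            mask[list(pick)] = True
            u = sum(a > b for a in pooled[mask] for b in pooled[~mask])
            if min(u, 9 - u) <= min(u_stat, 9 - u_stat):
                count += 1
            total += 1
        assert u_obs.pvalue == pytest.approx(count / total, abs=1e-12)
        assert u_obs.pvalue == pytest.approx(0.1, abs=1e-12)


class TestDunnAndT3:
    def test_dunn_symmetric_groups_agree_with_kruskal_direction(self, rng):
        arrays = [rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(2.5, 1, 15)]
        table = dunn_posthoc(["a", "b", "c"], arrays)
        ab = table.set_index(["group1", "group2"]).loc[("a", "b")]
        ac = table.set_index(["group1", "group2"]).loc[("a", "c")]
        assert ab["p_adjusted"] > ac["p_adjusted"]
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-12).all()

    def test_t3_reduces_to_welch_t_with_sidak_family(self, rng):
        arrays = [rng.normal(0, 1, 10), rng.normal(1, 3, 12), rng.normal(2, 2, 8)]
        table = dunnett_t3_posthoc(["a", "b", "c"], arrays)
        row = table.set_index(["group1", "group2"]).loc[("a", "b")]
        t_ref = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
        assert row["stat"] == pytest.approx(t_ref.statistic, rel=1e-10)
        assert row["p_raw"] == pytest.approx(t_ref.pvalue, rel=1e-10)
        assert row["p_adjusted"] == pytest.approx(1 - (1 - t_ref.pvalue) ** 3, rel=1e-10)


class TestBonferroni:
    def test_basic_arithmetic_and_cap(self):
        assert bonferroni_adjust([0.01], m=8)[0] == pytest.approx(0.08)
        assert bonferroni_adjust([0.3], m=8)[0] == 1.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10))
    def test_monotone_in_raw_pvalues(self, ps):
        adj = bonferroni_adjust(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([1.2])
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], m=1)
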