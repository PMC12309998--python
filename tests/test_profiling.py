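import io

import numpy as np
import pandas as pd
import pytest

import barleystress as bs
from barleystress.exceptions import BalanceError
from barleystress.profiling import balanced_two_way_ss

from conftest import make_long_frame


class TestChangePercentMatrix:
    def test_identity_and_forced_arithmetic(self):
        vals = {"C": 4.7, "Ds": 2.45}
        df = make_long_frame(["A"], ["C", "Ds", "Dd"], 2, ["GY"],
                             lambda g, t, r, tr: vals.get(t, 4.7))
        cm = bs.change_percent_matrix(bs.PhenotypeTable(df), "Ds")
        assert cm.loc["GY", "A"] == pytest.approx(100 * 2.45 / 4.7)
        cmd = bs.change_percent_matrix(bs.PhenotypeTable(df), "Dd")
        assert cmd.loc["GY", "A"] == 100.0

    def test_control_requested_is_error(self, tiny_table):
        with pytest.raises(ValueError, match="control"):
            bs.change_percent_matrix(tiny_table, "C")

    def test_noise_free_cohort_equals_spec_multipliers(self):
        from test_simulate import noise_free_spec
        spec = noise_free_spec()
        table, _ = bs.simulate_cohort(spec)
        cm = bs.change_percent_matrix(table, "Ds")
        for i, g in enumerate(spec.genotype_names):
            for tr in ("GY", "MSW"):
                expect = 100 * (spec.expected_mean(i, tr, "Ds")
                                / spec.expected_mean(i, tr, "C"))
                assert cm.loc[tr, g] == pytest.approx(expect)

    def test_invariant_under_trait_rescaling(self, default_cohort):
        _, table, _ = default_cohort
        cm = bs.change_percent_matrix(table, "Ds", traits=["GY", "MSW"])
        scaled = table.data.copy()
        mask = scaled["trait"] == "GY"
        scaled.loc[mask, "value"] *= 7.3
        cm2 = bs.change_percent_matrix(
            bs.PhenotypeTable(scaled), "Ds", traits=["GY", "MSW"])
        pd.testing.assert_frame_equal(cm, cm2)


class TestClustering:
    def _block_matrix(self):
        # three noise-free archetype blocks over 4 traits
        blocks = {"a": [120, 110, 50, 40], "b": [60, 55, 90, 85],
                  "c": [20, 10, 15, 30]}
        cols = {}
        for arch, profile in blocks.items():
            for i in range(4):
                cols[f"{arch}{i}"] = profile
        mat = pd.DataFrame(cols, index=["GY", "MSW", "SSW", "BIOM"], dtype=float)
        truth = pd.Series({c: c[0] for c in mat.columns})
        return mat, truth

    def test_separable_blocks_recovered_exactly(self):
        from sklearn.metrics import rand_score
        mat, truth = self._block_matrix()
        res = bs.cluster_axis(mat, k=3)
        assert rand_score(truth[res.labels.index], res.labels) == 1.0

    def test_group_numbering_by_descending_gy_change(self):
        mat, _ = self._block_matrix()
        res = bs.cluster_axis(mat, k=3)
        gy_means = mat.loc["GY"].groupby(res.labels).mean()
        assert list(gy_means.sort_index().index) == [1, 2, 3]
        assert gy_means[1] > gy_means[2] > gy_means[3]

    def test_duplicate_columns_merge_at_height_zero(self):
        mat, _ = self._block_matrix()
        res = bs.cluster_axis(mat, k=3)
        assert res.linkage[0, 2] == 0.0  # first merge joins duplicates

    def test_column_order_invariance(self):
        mat, _ = self._block_matrix()
        shuffled = mat[list(mat.columns[::-1])]
        l1 = bs.cluster_axis(mat, k=3).labels
        l2 = bs.cluster_axis(shuffled, k=3).labels
        assert (l1.sort_index() == l2.sort_index()).all()

    def test_k_one_returns_single_group(self):
        mat, _ = self._block_matrix()
        res = bs.cluster_axis(mat, k=1)
        assert set(res.labels) == {1}
        prof = bs.group_profile(mat, res.labels)
        np.testing.assert_allclose(prof[1], 100.0)

    def test_k_exceeding_axis_raises(self):
        mat, _ = self._block_matrix()
        with pytest.raises(ValueError, match="exceeds"):
            bs.cluster_axis(mat, k=13)

    def test_newick_export_parses(self):
        from Bio import Phylo
        mat, _ = self._block_matrix()
        res = bs.cluster_axis(mat, k=3)
        tree = Phylo.read(io.StringIO(res.to_newick()), "newick")
        leaves = {cl.name for cl in tree.get_terminals()}
        assert leaves == set(mat.columns)

    def test_trait_axis_clustering(self, default_cohort):
        _, table, _ = default_cohort
        cm = bs.change_percent_matrix(table, "Ds")
        res = bs.cluster_axis(cm, axis="traits", k=4)
        assert set(res.labels.index) == set(cm.index)


class TestGroupProfile:
    def test_two_group_forced_arithmetic(self):
        mat = pd.DataFrame({"g1": [50.0], "g2": [150.0]}, index=["GY"])
        labels = pd.Series({"g1": 1, "g2": 2})
        prof = bs.group_profile(mat, labels)
        assert prof.loc["GY", 1] == 50.0
        assert prof.loc["GY", 2] == 150.0

    def test_members_recorded(self):
        mat = pd.DataFrame({"g1": [50.0], "g2": [150.0]}, index=["GY"])
        prof = bs.group_profile(mat, pd.Series({"g1": 1, "g2": 2}))
        assert prof.attrs["members"] == {1: ["g1"], 2: ["g2"]}


class TestSeparationLetters:
    def test_widely_separated_groups_distinct_letters(self):
        rng = np.random.default_rng(0)
        values = pd.Series(np.r_[rng.normal(0, 0.1, 8),
                                 rng.normal(5, 0.1, 8),
                                 rng.normal(10, 0.1, 8)])
        labels = pd.Series([1] * 8 + [2] * 8 + [3] * 8)
        letters = bs.group_separation_letters(values, labels)
        assert len({letters[1], letters[2], letters[3]}) == 3

    def test_identical_distributions_share_letter(self):
        rng = np.random.default_rng(1)
        pooled = rng.normal(0, 1, 24)
        values = pd.Series(pooled)
        labels = pd.Series([1] * 8 + [2] * 8 + [3] * 8)
        letters = bs.group_separation_letters(values, labels)
        assert letters[1] == letters[2] == letters[3]

    def test_degenerate_equal_values_single_letter(self):
        values = pd.Series([3.0] * 12)
        labels = pd.Series([1] * 6 + [2] * 6)
        assert bs.group_separation_letters(values, labels) == {1: "a", 2: "a"}

    def test_requires_two_members_per_group(self):
        values = pd.Series([1.0, 2.0, 3.0])
        labels = pd.Series([1, 1, 2])
        with pytest.raises(ValueError):
            bs.group_separation_letters(values, labels)


class TestAnovaPartition:
    def test_pure_treatment_effect(self):
        vals = {"C": 1.0, "Ds": 2.0, "Dd": 3.0}
        df = make_long_frame(["A", "B", "D"], ["C", "Ds", "Dd"], 3, ["GY"],
                             lambda g, t, r, tr: vals[t])
        part = bs.anova_ss_partition(bs.PhenotypeTable(df), "GY")
        assert part.ss_pct["treatment"] == pytest.approx(100.0)
        assert part.ss_pct["genotype"] == pytest.approx(0.0)

    def test_ss_decomposition_sums_to_total(self):
        rng = np.random.default_rng(4)
        y = rng.normal(10, 2, size=(6, 3, 4))
        res = balanced_two_way_ss(y)
        parts = sum(res["ss"][k] for k in
                    ("genotype", "treatment", "interaction", "residual"))
        assert parts == pytest.approx(res["ss"]["total"], rel=1e-10)

    def test_matches_statsmodels_anova(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(5)
        df = make_long_frame(["A", "B", "D", "E"], ["C", "Ds", "Dd"], 3,
                             ["GY"], lambda g, t, r, tr: 0.0)
        df["value"] = rng.normal(10, 2, len(df))
        part = bs.anova_ss_partition(bs.PhenotypeTable(df), "GY")
        fit = smf.ols("value ~ C(genotype) * C(treatment)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=1)
        assert part.ss["genotype"] == pytest.approx(
            tab.loc["C(genotype)", "sum_sq"], rel=1e-9)
        assert part.ss["treatment"] == pytest.approx(
            tab.loc["C(treatment)", "sum_sq"], rel=1e-9)
        assert part.ss["interaction"] == pytest.approx(
            tab.loc["C(genotype):C(treatment)", "sum_sq"], rel=1e-9)
        assert part.ss["residual"] == pytest.approx(
            tab.loc["Residual", "sum_sq"], rel=1e-9)

    def test_unbalanced_refused(self, tiny_table):
        df = tiny_table.data.drop(index=0)
        with pytest.raises(BalanceError, match="balance"):
            bs.anova_ss_partition(bs.PhenotypeTable(df), "GY")

    def test_strong_genotype_effect_dominates_for_tiller_like_trait(self):
        # treatment barely moves the trait while genotypes differ strongly
        spec = bs.CohortSpec(
            n_genotypes=8, row_type_counts={"2R": 4, "6R": 4}, n_reps=4,
            baseline_means={"RT": {"2R": 6.0, "6R": 12.0}},
            treatment_effects={"RT": {"Ds": {"2R": 1.02, "6R": 1.02},
                                      "Dd": {"2R": 1.05, "6R": 1.05}}},
            variance=bs.VarianceSpec(scale="log", Vg=0.09, Vge=0.001, Vr=0.005),
            seed=9,
        )
        table, _ = bs.simulate_cohort(spec)
        part = bs.anova_ss_partition(table, "RT")
        assert part.ss_pct["genotype"] > part.ss_pct["treatment"]
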