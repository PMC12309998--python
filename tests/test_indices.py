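import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import barleystress as bs
from barleystress.exceptions import ConfigError

from _oracles import brute_force_consensus
from conftest import make_long_frame

positive = st.floats(min_value=0.1, max_value=100.0,
                     allow_nan=False, allow_infinity=False)


class TestScalarFormulas:
    def test_stress_intensity(self):
        assert bs.stress_intensity(2.0, 4.0) == 0.5
        assert bs.stress_intensity(4.0, 4.0) == 0.0
        with pytest.raises(ValueError):
            bs.stress_intensity(1.0, 0.0)

    @pytest.mark.parametrize("yp,ys,si,expected", [
        (4.0, 2.0, 0.5, 1.0),   # genotype at panel-average loss
        (4.0, 3.0, 0.5, 0.5),
        (4.0, 4.0, 0.5, 0.0),   # zero-loss genotype
    ])
    def test_dsi(self, yp, ys, si, expected):
        assert bs.dsi(yp, ys, si) == pytest.approx(expected)

    @pytest.mark.parametrize("yp,ys,gyp,expected", [
        (4.0, 4.0, 4.0, 1.0),   # panel-mean genotype with no loss
        (4.0, 2.0, 4.0, 0.5),
        (4.0, 0.0, 4.0, 0.0),   # total loss
    ])
    def test_sti(self, yp, ys, gyp, expected):
        assert bs.sti(yp, ys, gyp) == pytest.approx(expected)

    def test_ysi_and_tol(self):
        assert bs.ysi(4.0, 2.0) == 0.5
        assert bs.tol(4.0, 2.0) == 2.0
        assert bs.ysi(4.0, 4.0) == 1.0
        assert bs.tol(4.0, 4.0) == 0.0

    @given(yp=positive, ys=positive)
    def test_tol_equals_yp_times_one_minus_ysi(self, yp, ys):
        assert bs.tol(yp, ys) == pytest.approx(yp * (1 - bs.ysi(yp, ys)))


class TestStressMean:
    def test_forced_arithmetic(self):
        vals = {"C": 4.7, "Ds": 2.45, "Dd": 2.2}
        df = make_long_frame(["A"], ["C", "Ds", "Dd"], 4, ["GY"],
                             lambda g, t, r, tr: vals[t])
        ys = bs.stress_mean(bs.PhenotypeTable(df), "GY")
        assert ys["A"] == pytest.approx((2.45 + 2.2) / 2)

    def test_identity_when_equal(self, tiny_table):
        means = tiny_table.cell_means("GY")
        ys = bs.stress_mean(tiny_table, "GY")
        pd.testing.assert_series_equal(
            ys, means[["Ds", "Dd"]].mean(axis=1), check_names=False)

    def test_missing_treatment_suggests_single_mode(self):
        df = make_long_frame(["A"], ["C", "Ds"], 2, ["GY"], lambda *a: 2.0)
        with pytest.raises(ConfigError, match="single-treatment"):
            bs.stress_mean(bs.PhenotypeTable(df), "GY", mode="both")
        ok = bs.stress_mean(bs.PhenotypeTable(df), "GY", mode="Ds-only")
        assert ok["A"] == 2.0


class TestComputeIndices:
    def test_dsi_is_one_at_panel_average_ratio(self):
        # both genotypes share Ys/Yp = grand ratio -> DSI exactly 1
        vals = {("A", "C"): 4.0, ("A", "Ds"): 2.0, ("A", "Dd"): 2.0,
                ("B", "C"): 8.0, ("B", "Ds"): 4.0, ("B", "Dd"): 4.0}
        df = make_long_frame(["A", "B"], ["C", "Ds", "Dd"], 2, ["GY"],
                             lambda g, t, r, tr: vals[(g, t)])
        idx = bs.compute_indices(bs.PhenotypeTable(df))
        np.testing.assert_allclose(idx["DSI"], 1.0)

    def test_oracle_recomputation_on_cohort(self, default_cohort):
        _, table, _ = default_cohort
        idx = bs.compute_indices(table)
        means = table.cell_means("GY")
        ys = (means["Ds"] + means["Dd"]) / 2
        si = 1 - ys.mean() / means["C"].mean()
        np.testing.assert_allclose(idx["SI"], si)
        np.testing.assert_allclose(
            idx["STI"], ys * means["C"] / means["C"].mean() ** 2)

    @given(c=st.floats(min_value=0.01, max_value=50))
    def test_scale_invariance(self, c, default_cohort):
        _, table, _ = default_cohort
        idx = bs.compute_indices(table)
        scaled = table.data.copy()
        scaled["value"] = scaled["value"] * c
        idx2 = bs.compute_indices(bs.PhenotypeTable(scaled))
        for col in ("SI", "DSI", "STI", "YSI"):
            np.testing.assert_allclose(idx2[col], idx[col], rtol=1e-9)
        np.testing.assert_allclose(idx2["TOL"], c * idx["TOL"], rtol=1e-9)

    def test_monotone_in_ys(self):
        # raising one genotype's stress mean: DSI/TOL fall, STI/YSI rise
        si, yp, gyp = 0.5, 4.0, 5.0
        ys = np.linspace(0.5, 4.0, 9)
        assert np.all(np.diff(bs.dsi(yp, ys, si)) < 0)
        assert np.all(np.diff(bs.tol(yp, ys)) < 0)
        assert np.all(np.diff(bs.sti(yp, ys, gyp)) > 0)
        assert np.all(np.diff(bs.ysi(yp, ys)) > 0)


class TestClassification:
    def _frame(self, rows):
        return pd.DataFrame(rows).set_index("genotype")

    def test_joint_threshold_labels(self):
        df = self._frame([
            {"genotype": "T", "DSI": 0.3, "STI": 1.2, "YSI": 0.8, "TOL": 0.1},
            {"genotype": "M1", "DSI": 1.0, "STI": 0.6, "YSI": 0.5, "TOL": 2.0},
            {"genotype": "M2", "DSI": 1.1, "STI": 0.5, "YSI": 0.45, "TOL": 2.2},
            {"genotype": "S", "DSI": 1.8, "STI": 0.1, "YSI": 0.2, "TOL": 4.0},
        ])
        out = bs.classify_tolerance(df)
        assert out.loc["T", "label"] == "most_tolerant"
        assert out.loc["S", "label"] == "most_susceptible"
        assert out.loc["M1", "label"] == "intermediate"

    def test_dsi_boundary_is_sensitive(self):
        df = self._frame([
            {"genotype": "X", "DSI": 1.0, "STI": 0.9, "YSI": 0.5, "TOL": 1.0},
            {"genotype": "Y", "DSI": 0.99, "STI": 0.9, "YSI": 0.5, "TOL": 1.0},
        ])
        out = bs.classify_tolerance(df)
        assert out.loc["X", "dsi_class"] == "sensitive"
        assert out.loc["Y", "dsi_class"] == "tolerant"

    def test_sti_bands(self):
        df = self._frame([
            {"genotype": "H", "DSI": 1, "STI": 1.0, "YSI": 1, "TOL": 0},
            {"genotype": "M", "DSI": 1, "STI": 0.5, "YSI": 1, "TOL": 0},
            {"genotype": "L", "DSI": 1, "STI": 0.49, "YSI": 1, "TOL": 0},
        ])
        out = bs.classify_tolerance(df)
        assert list(out["sti_class"]) == ["high", "moderate", "low"]

    def test_missing_index_unclassified(self):
        df = self._frame([
            {"genotype": "A", "DSI": np.nan, "STI": 1.0, "YSI": 0.9, "TOL": 0.1},
            {"genotype": "B", "DSI": 0.5, "STI": 1.0, "YSI": 0.9, "TOL": 0.1},
        ])
        out = bs.classify_tolerance(df)
        assert out.loc["A", "label"] == "unclassified"


class TestConsensusRank:
    def test_dominant_genotype_ranks_first(self):
        df = pd.DataFrame({
            "DSI": [0.2, 1.0, 1.5], "TOL": [0.5, 2.0, 3.0],
            "STI": [1.5, 0.8, 0.2], "YSI": [0.9, 0.5, 0.2],
        }, index=["best", "mid", "worst"])
        out = bs.consensus_rank(df)
        assert out.index[0] == "best"
        assert out.loc["best", "consensus_rank"] == 1

    def test_identical_genotypes_break_ties_by_name(self):
        df = pd.DataFrame({
            "DSI": [1.0, 1.0], "TOL": [2.0, 2.0],
            "STI": [0.5, 0.5], "YSI": [0.5, 0.5],
        }, index=["zeta", "alpha"])
        out = bs.consensus_rank(df)
        assert list(out.index) == ["alpha", "zeta"]
        assert list(out["consensus_rank"]) == [1, 2]

    def test_matches_brute_force_oracle(self, default_cohort):
        _, table, _ = default_cohort
        idx = bs.compute_indices(table)
        out = bs.consensus_rank(idx)
        oracle = brute_force_consensus(idx)
        for g, rank in oracle.items():
            assert out.loc[g, "consensus_rank"] == rank
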