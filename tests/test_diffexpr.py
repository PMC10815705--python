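import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clockko import contrast, contrast_all, ddct, filter_expressed

from conftest import make_study


def tpm_from_log2(wt, mut, genotype="NDKO"):
    """Single-gene study whose log2(TPM+1) values equal wt/mut exactly."""
    return make_study(
        {"G1": {"WT": list(2.0 ** np.array(wt) - 1), genotype: list(2.0 ** np.array(mut) - 1)}}
    )


class TestFilterExpressed:
    def test_quarter_quantile_keeps_top_two_of_eight(self):
        study = make_study(
            {f"G{i}": {"WT": [float(i)] * 2, "NDKO": [float(i)] * 2} for i in range(1, 9)}
        )
        kept = filter_expressed(study, 0.25)
        assert sorted(kept.tpm.index) == ["G7", "G8"]

    def test_quantile_one_is_identity(self):
        study = make_study(
            {f"G{i}": {"WT": [float(i)] * 2, "NDKO": [1.0] * 2} for i in range(5)}
        )
        kept = filter_expressed(study, 1.0)
        assert list(kept.tpm.index) == list(study.tpm.index)
        assert list(kept.tpm.columns) == list(study.tpm.columns)

    def test_cutoff_ties_broken_lexicographically(self):
        """Matches an exhaustive sort-with-tiebreak oracle when three genes
        tie exactly at the retention cutoff."""
        means = {"A": 9, "B": 8, "C": 5, "D": 5, "E": 5, "F": 4, "G": 3, "H": 2, "I": 1, "J": 1}
        study = make_study(
            {g: {"WT": [float(m)] * 2, "NDKO": [float(m)] * 2} for g, m in means.items()}
        )
        kept = filter_expressed(study, 0.4)  # floor(0.4*10) = 4 genes
        oracle = [g for g, _ in sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))][:4]
        assert sorted(kept.tpm.index) == sorted(oracle)
        assert sorted(kept.tpm.index) == ["A", "B", "C", "D"]

    @pytest.mark.parametrize("q", [0.0, -0.1, 1.5])
    def test_invalid_quantile_rejected(self, q):
        study = make_study({"G1": {"WT": [1.0, 1.0], "NDKO": [1.0, 1.0]}})
        with pytest.raises(ValueError, match="quantile"):
            filter_expressed(study, q)


class TestContrast:
    def test_identical_groups_give_p_one_no_flag(self):
        study = tpm_from_log2([1, 2, 3, 4], [1, 2, 3, 4])
        row = contrast(study, "NDKO").iloc[0]
        assert row["p"] == pytest.approx(1.0)
        assert not row["deg_up"] and not row["deg_down"]

    def test_textbook_pooled_t(self):
        """log2 groups (1,2,3,4) vs (3,4,5,6): t = 2.191 on 6 df, p ~ 0.0710."""
        study = tpm_from_log2([1, 2, 3, 4], [3, 4, 5, 6])
        row = contrast(study, "NDKO").iloc[0]
        assert row["p"] == pytest.approx(0.07098765432, rel=1e-9)

    def test_threshold_semantics_flag_threefold_increase(self):
        study = make_study(
            {"G1": {"WT": [9.0, 10.0, 10.0, 11.0], "NDKO": [29.0, 30.0, 30.0, 31.0]}}
        )
        row = contrast(study, "NDKO").iloc[0]
        assert row["fc"] == pytest.approx(3.0)
        assert row["p"] < 0.05
        assert row["deg_up"] and not row["deg_down"]

    def test_strict_inequality_at_fc_threshold(self):
        """fc exactly 1.5 must not be flagged (criterion is > 1.5)."""
        study = make_study(
            {"G1": {"WT": [9.0, 10.0, 11.0, 10.0], "NDKO": [13.5, 15.0, 16.5, 15.0]}}
        )
        row = contrast(study, "NDKO").iloc[0]
        assert row["fc"] == pytest.approx(1.5)
        assert not row["deg_up"]

    def test_zero_variance_degeneracies(self):
        same = make_study({"G1": {"WT": [5.0] * 3, "NDKO": [5.0] * 3}})
        assert contrast(same, "NDKO").iloc[0]["p"] == 1.0
        diff = make_study({"G1": {"WT": [5.0] * 3, "NDKO": [20.0] * 3}})
        row = contrast(diff, "NDKO").iloc[0]
        assert row["p"] == 0.0 and row["degenerate"]

    def test_zero_over_zero_fc_undefined(self):
        study = make_study(
            {"G1": {"WT": [0.0, 0.0], "NDKO": [0.0, 0.0]},
             "G2": {"WT": [1.0, 1.0], "NDKO": [2.0, 2.0]}}
        )
        out = contrast(study, "NDKO").set_index("gene")
        assert out.loc["G1", "fc_undefined"]
        assert np.isnan(out.loc["G1", "fc"])
        assert not out.loc["G1", "deg_up"] and not out.loc["G1", "deg_down"]

    def test_wt_contrast_rejected(self):
        study = tpm_from_log2([1, 2], [1, 2])
        with pytest.raises(ValueError, match="WT"):
            contrast(study, "WT")

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        wt=st.lists(st.floats(0.1, 8.0), min_size=3, max_size=6),
        mut=st.lists(st.floats(0.1, 8.0), min_size=3, max_size=6),
    )
    def test_group_swap_negates_log2fc_and_keeps_p(self, wt, mut):
        fwd = tpm_from_log2(wt, mut)
        rev = tpm_from_log2(mut, wt)
        a = contrast(fwd, "NDKO").iloc[0]
        b = contrast(rev, "NDKO").iloc[0]
        assert 0.0 <= a["p"] <= 1.0
        assert a["p"] == pytest.approx(b["p"], rel=1e-9)
        if np.isfinite(a["log2fc"]) and np.isfinite(b["log2fc"]):
            assert a["log2fc"] == pytest.approx(-b["log2fc"], abs=1e-9)

    def test_gene_permutation_equivariance(self, planted_study):
        study, _ = planted_study
        sub = study.tpm.head(50)
        perm = sub.sample(frac=1.0, random_state=0)
        from clockko import ExpressionStudy

        a = contrast(ExpressionStudy(sub, study.design), "N1KO").set_index("gene")
        b = contrast(ExpressionStudy(perm, study.design), "N1KO").set_index("gene")
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_power_and_type_one_error_on_planted_data(self):
        """At the default thresholds, planted 3-fold DEGs are recovered with
        power >= 0.95 and null genes are flagged at <= 7%."""
        from clockko import SimConfig, simulate_expression

        study, truth = simulate_expression(
            SimConfig(n_genes=2000, replicate_sd=0.15, seed=424242)
        )
        contrasts = contrast_all(study)
        nd = contrasts[contrasts["genotype"] == "NDKO"].set_index("gene")
        planted = truth[truth["delta_nd"] != 0]
        flagged = nd.loc[planted.index, "deg_up"] | nd.loc[planted.index, "deg_down"]
        assert flagged.mean() >= 0.95
        nulls = truth.index[truth["label"] == "null"]
        any_flag = (
            contrasts[contrasts["gene"].isin(nulls)]
            .groupby("gene")[["deg_up", "deg_down"]]
            .any()
            .any(axis=1)
        )
        assert any_flag.mean() <= 0.07


class TestDdct:
    def qpcr(self, rows):
        return pd.DataFrame(rows, columns=["sample", "group", "ct_target", "ct_reference"])

    def test_one_cycle_shift_doubles_expression(self):
        table = self.qpcr([("c1", "WT", 20.0, 15.0), ("t1", "KO", 19.0, 15.0)])
        out = ddct(table, "WT").set_index("sample")
        assert out.loc["t1", "rel_expr"] == pytest.approx(2.0)
        assert out.loc["c1", "rel_expr"] == pytest.approx(1.0)

    def test_sample_at_control_mean_is_one(self):
        table = self.qpcr(
            [("c1", "WT", 20.0, 15.0), ("c2", "WT", 22.0, 17.0), ("t1", "KO", 21.0, 16.0)]
        )
        out = ddct(table, "WT").set_index("sample")
        assert out.loc["t1", "rel_expr"] == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        table = self.qpcr([("c1", "WT", 20.0, 15.0), ("t1", "KO", 21.3, 15.0)])
        out = ddct(table, "WT").set_index("sample")
        assert out.loc["t1", "rel_expr"] == pytest.approx(2.0 ** -1.3, rel=1e-12)

    def test_missing_ct_dropped_with_warning(self):
        table = self.qpcr([("c1", "WT", 20.0, 15.0), ("t1", "KO", np.nan, 15.0)])
        with pytest.warns(UserWarning, match="missing Ct"):
            out = ddct(table, "WT")
        assert list(out["sample"]) == ["c1"]

    def test_control_group_geometric_mean_is_one(self):
        table = self.qpcr(
            [("c1", "WT", 20.0, 15.0), ("c2", "WT", 21.0, 15.5), ("c3", "WT", 19.5, 15.2)]
        )
        out = ddct(table, "WT")
        ctrl = out.loc[out["group"] == "WT", "rel_expr"]
        assert np.exp(np.log(ctrl).mean()) == pytest.approx(1.0, abs=1e-12)
        assert (out["rel_expr"] > 0).all()
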