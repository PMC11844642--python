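import math

import numpy as np
import pandas as pd
import pytest

from qpcrmlm import (
    CTTable,
    DesignMatrix,
    InsufficientDataError,
    ModelSpec,
    RankDeficiencyError,
    analyze_ancova,
    build_design,
    coefficient_test,
    dct_test,
    fit_ols,
    parse_model_string,
    scale_gene_efficiency,
    Efficiency,
)
from qpcrmlm.mlm import ModelSpecError, TermLookupError


def _random_design(rng, n, p):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    return DesignMatrix(X, ["(Intercept)"] + [f"x{i}" for i in range(1, p)])


class TestBuildDesign:
    def test_worked_example_design(self, table2, table2_spec):
        design, y, samples = build_design(table2, table2_spec)
        assert design.matrix.shape == (10, 7)
        assert design.column_names == [
            "(Intercept)", "Donor-KK22F", "Donor-KK27H", "Donor-KK29H",
            "Donor-KK32G", "Treatment-ETI", "GAPDH"]
        assert design.baseline_levels == {"Donor": "KK18G", "Treatment": "DMSO"}
        assert samples == table2.samples
        np.testing.assert_allclose(y, table2.wide()["MMP10"])

    def test_minimal_two_level_design(self):
        rows = [(f"s{i}", f"d{i}", "ctl" if i < 2 else "trt", "G", 20.0 + i)
                for i in range(4)]
        t = CTTable(pd.DataFrame(
            rows, columns=["sample", "subject", "treatment", "gene", "ct"]))
        design, y, _ = build_design(t, ModelSpec(response="G"))
        assert design.matrix.shape == (4, 2)

    def test_duplicated_reference_is_rank_error(self, table2):
        spec = ModelSpec(response="MMP10", treatment="Treatment",
                         control_level="DMSO",
                         reference_genes=("GAPDH", "GAPDH"))
        with pytest.raises(RankDeficiencyError, match="GAPDH"):
            build_design(table2, spec)

    def test_single_level_factor_rejected(self, table2):
        dmso_only = CTTable(table2.data[table2.data["treatment"] == "DMSO"])
        with pytest.raises(ModelSpecError, match="single observed level"):
            build_design(dmso_only, ModelSpec(response="MMP10"))

    def test_missing_cells_dropped_and_logged(self, table2, caplog):
        df = table2.data.copy()
        df.loc[(df["sample"] == "KK22F DMSO") & (df["gene"] == "MMP10"), "ct"] = np.nan
        t = CTTable(df)
        with caplog.at_level("INFO", logger="qpcrmlm"):
            _, y, samples = build_design(
                t, ModelSpec(response="MMP10", reference_genes=("GAPDH",)))
        assert len(samples) == 9 and "KK22F DMSO" not in samples
        assert "dropped 1" in caplog.text

    def test_response_cannot_be_reference(self):
        with pytest.raises(ModelSpecError):
            ModelSpec(response="G", reference_genes=("G",))


class TestFitOLS:
    def test_matches_statsmodels_on_fixture(self, table2, table2_spec):
        sm = pytest.importorskip("statsmodels.api")
        design, y, _ = build_design(table2, table2_spec)
        fit = fit_ols(design, y)
        ref = sm.OLS(y, design.matrix).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-8)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, atol=1e-8)
        np.testing.assert_allclose(fit.p_values, ref.pvalues, atol=1e-10)
        assert fit.residual_df == ref.df_resid

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pseudoinverse_oracle(self, seed):
        # brute-force normal-equations solve on random small designs
        rng = np.random.default_rng(seed)
        n, p = rng.integers(6, 13), rng.integers(2, 7)
        while n <= p:
            n = rng.integers(6, 13)
        design = _random_design(rng, int(n), int(p))
        y = rng.normal(size=int(n))
        fit = fit_ols(design, y)
        np.testing.assert_allclose(
            fit.coefficients, np.linalg.pinv(design.matrix) @ y, atol=1e-8)

    def test_exact_linear_response(self, table2, table2_spec):
        design, _, _ = build_design(table2, table2_spec)
        y = design.matrix[:, design.column_names.index("GAPDH")]
        fit = fit_ols(design, y)
        expected = np.zeros(7)
        expected[design.column_names.index("GAPDH")] = 1.0
        np.testing.assert_allclose(fit.coefficients, expected, atol=1e-8)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        design = _random_design(rng, 12, 5)
        y = rng.normal(size=12)
        fit = fit_ols(design, y)
        scale = np.abs(design.matrix).max() * np.abs(y).max()
        assert np.abs(design.matrix.T @ fit.residuals).max() < 1e-8 * max(scale, 1)

    def test_reconstruction_and_r2(self, rng):
        design = _random_design(rng, 10, 3)
        y = rng.normal(size=10)
        fit = fit_ols(design, y)
        np.testing.assert_allclose(fit.fitted + fit.residuals, y, atol=1e-12)
        assert 0.0 <= fit.r_squared <= 1.0
        assert fit.residual_df == 7

    def test_insufficient_data(self, rng):
        X = np.column_stack([np.ones(3), rng.normal(size=(3, 3))])
        with pytest.raises(InsufficientDataError, match="n > p"):
            DesignMatrix(X, ["(Intercept)", "a", "b", "c"])


class TestAnalyzeAncova:
    def test_reproduces_published_fit(self, table2, table2_spec):
        # values cross-checked against an independent OLS (statsmodels / R lm)
        res = analyze_ancova(table2, table2_spec)
        s = res.summary.set_index("term")
        assert list(s.index) == ["Donor-KK22F", "Donor-KK27H", "Donor-KK29H",
                                 "Donor-KK32G", "Treatment-ETI", "GAPDH"]
        assert s.loc["Treatment-ETI", "estimate"] == pytest.approx(0.944548, abs=1e-5)
        assert s.loc["Treatment-ETI", "p_value"] == pytest.approx(0.013770, abs=1e-5)
        assert s.loc["GAPDH", "estimate"] == pytest.approx(0.342461, abs=1e-5)

    def test_coefficient_test_passthrough(self, table2, table2_spec):
        res = analyze_ancova(table2, table2_spec)
        t = coefficient_test(res.fit, "Treatment-ETI")
        row = res.summary.set_index("term").loc["Treatment-ETI"]
        assert t.estimate == row["estimate"] and t.p_value == row["p_value"]
        assert t.df == res.fit.residual_df

    def test_unknown_term_lists_available(self, table2, table2_spec):
        res = analyze_ancova(table2, table2_spec)
        with pytest.raises(TermLookupError, match="Treatment-ETI"):
            coefficient_test(res.fit, "Treatment-Placebo")

    def test_treatment_only_model_equals_pooled_t(self, table2):
        # 2-group OLS and the pooled two-sample t are algebraically identical
        res = analyze_ancova(table2, ModelSpec(
            response="MMP10", treatment="Treatment", control_level="DMSO"))
        ols_p = res.summary.set_index("term").loc["Treatment-ETI", "p_value"]
        t = dct_test(table2, "MMP10", "DMSO")
        assert ols_p == pytest.approx(t.p_value, abs=1e-12)
        assert res.summary.set_index("term").loc[
            "Treatment-ETI", "estimate"] == pytest.approx(t.estimate, abs=1e-12)

    def test_duplicated_groups_give_zero_effect(self, table2):
        # make each ETI sample an exact copy of its donor's DMSO sample
        df = table2.data.copy()
        wide = table2.wide()
        for donor in df["subject"].unique():
            for gene in table2.genes:
                df.loc[(df["subject"] == donor) & (df["treatment"] == "ETI")
                       & (df["gene"] == gene), "ct"] = wide.loc[f"{donor} DMSO", gene]
        # donor dummies would be exactly collinear with GAPDH here (one
        # GAPDH value per donor), so fit the donor-free model
        res = analyze_ancova(CTTable(df), ModelSpec(
            response="MMP10", treatment="Treatment", control_level="DMSO",
            reference_genes=("GAPDH",)))
        assert res.summary.set_index("term").loc[
            "Treatment-ETI", "estimate"] == pytest.approx(0.0, abs=1e-10)
        with pytest.raises(RankDeficiencyError):
            analyze_ancova(CTTable(df), ModelSpec(
                response="MMP10", treatment="Treatment", control_level="DMSO",
                nuisance_factors=("Donor",), reference_genes=("GAPDH",)))


class TestScaleInvariance:
    @pytest.mark.parametrize("c", [0.5, math.log2(1.9), 3.0])
    def test_reference_rescaling_preserves_inference(self, table2, table2_spec, c):
        base = analyze_ancova(table2, table2_spec).summary.set_index("term")
        df = table2.data.copy()
        df.loc[df["gene"] == "GAPDH", "ct"] *= c
        scaled = analyze_ancova(CTTable(df), table2_spec).summary.set_index("term")
        for term in base.index:
            if term == "GAPDH":
                continue
            assert scaled.loc[term, "t"] == pytest.approx(
                base.loc[term, "t"], rel=1e-10)
            assert scaled.loc[term, "p_value"] == pytest.approx(
                base.loc[term, "p_value"], rel=1e-10)

    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_global_rescaling_preserves_treatment_inference(
            self, table2, table2_spec, c):
        base = analyze_ancova(table2, table2_spec).summary.set_index("term")
        df = table2.data.copy()
        df["ct"] *= c
        scaled = analyze_ancova(CTTable(df), table2_spec).summary.set_index("term")
        assert scaled.loc["Treatment-ETI", "p_value"] == pytest.approx(
            base.loc["Treatment-ETI", "p_value"], rel=1e-10)

    def test_efficiency_rescaling_is_a_scale_change(self, table2, table2_spec):
        base = analyze_ancova(table2, table2_spec).summary.set_index("term")
        scaled_table = scale_gene_efficiency(table2, "GAPDH", Efficiency(0.9))
        scaled = analyze_ancova(scaled_table, table2_spec).summary.set_index("term")
        assert scaled.loc["Treatment-ETI", "p_value"] == pytest.approx(
            base.loc["Treatment-ETI", "p_value"], rel=1e-10)


class TestParseModelString:
    def test_worked_example(self, table2):
        spec = parse_model_string("MMP10 ~ Donor + Treatment + GAPDH", table2,
                                  control_level="DMSO")
        assert spec.response == "MMP10"
        assert spec.nuisance_factors == ("Donor",)
        assert spec.reference_genes == ("GAPDH",)
        assert spec.control_level == "DMSO"

    @pytest.mark.parametrize("formula", [
        "MMP10 ~ Donor + GAPDH",        # no treatment factor
        "ACTB ~ Treatment + GAPDH",     # unknown response
        "MMP10 ~ Plate + Treatment",    # unknown factor
        "MMP10 ~ Treatment ~ GAPDH",    # malformed
    ])
    def test_bad_formulas_rejected(self, table2, formula):
        with pytest.raises(ModelSpecError):
            parse_model_string(formula, table2, control_level="DMSO")
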