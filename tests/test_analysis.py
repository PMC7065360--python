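"""RCBD inference: Type-II Wald F, predictions/LSDs, diagnostics, AR1."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import setgrowth as sg
from setgrowth import EstimabilityError, ParameterError
from setgrowth.traits import TraitTable

from conftest import ENDPOINTS


def balanced_table(rng=None, n_blocks=4, zn=(0, 10, 40, 90), amf=("+", "-"),
                   effects=None, sigma=1.0):
    """A balanced RCBD trait table with optional additive effects."""
    rng = rng or np.random.default_rng(0)
    rows = []
    for b in range(n_blocks):
        for z in zn:
            for a in amf:
                mu = 10.0
                if effects:
                    mu += effects.get(("block", b), 0.0)
                    mu += effects.get(("zn", z), 0.0)
                    mu += effects.get(("amf", a), 0.0)
                    mu += effects.get(("cell", (z, a)), 0.0)
                rows.append(
                    {
                        "subject": f"s{b}_{z}_{a}",
                        "Block": f"B{b + 1}",
                        "Zn": z,
                        "AMF": a,
                        "y": mu + sigma * rng.standard_normal(),
                    }
                )
    df = pd.DataFrame(rows).set_index("subject")
    return TraitTable(df, factors=("Block", "Zn", "AMF"), traits=("y",),
                      block="Block")


def classical_balanced_anova(df, response="y"):
    """Independent sums-of-squares oracle for the balanced two-way RCBD:
    SS from marginal means, F = MS_term / MS_residual."""
    y = df[response]
    grand = y.mean()
    n = len(df)
    ss = {}
    for term, cols in (("Block", ["Block"]), ("Zn", ["Zn"]), ("AMF", ["AMF"])):
        means = df.groupby(cols, observed=True)[response].mean()
        counts = df.groupby(cols, observed=True)[response].count()
        ss[term] = float((counts * (means - grand) ** 2).sum())
    cell_means = df.groupby(["Zn", "AMF"], observed=True)[response].mean()
    cell_counts = df.groupby(["Zn", "AMF"], observed=True)[response].count()
    ss_cells = float((cell_counts * (cell_means - grand) ** 2).sum())
    ss["Zn:AMF"] = ss_cells - ss["Zn"] - ss["AMF"]
    dfs = {
        "Block": df["Block"].nunique() - 1,
        "Zn": df["Zn"].nunique() - 1,
        "AMF": df["AMF"].nunique() - 1,
    }
    dfs["Zn:AMF"] = dfs["Zn"] * dfs["AMF"]
    ss_model = sum(ss.values())
    ss_total = float(((y - grand) ** 2).sum())
    df_resid = n - 1 - sum(dfs.values())
    ms_resid = (ss_total - ss_model) / df_resid
    return {t: (ss[t] / dfs[t]) / ms_resid for t in ss}, df_resid


SPEC = sg.ModelSpec(response="y")


class TestFitAndWald:
    def test_hand_computed_two_by_two_anova(self):
        """2 blocks x 2 treatments with constructed effects and a +/-0.1
        residual pattern; F checked against the hand ANOVA."""
        rows = []
        resid = {("B1", "T1"): 0.1, ("B1", "T2"): -0.1,
                 ("B2", "T1"): -0.1, ("B2", "T2"): 0.1}
        for b, beff in (("B1", 0.0), ("B2", 1.0)):
            for t, teff in (("T1", 0.0), ("T2", 2.0)):
                rows.append({"subject": f"{b}{t}", "Block": b, "Trt": t,
                             "y": 5.0 + beff + teff + resid[(b, t)]})
        df = pd.DataFrame(rows).set_index("subject")
        table = TraitTable(df, factors=("Block", "Trt"), traits=("y",),
                           block="Block")
        fit = sg.fit_rcbd(table, sg.ModelSpec(response="y", factors=("Trt",)))
        wt = sg.wald_tests(fit).set_index("term")
        # hand ANOVA: SS_trt = 4 (=2^2), SS_block = 1, SS_resid = 0.04, df=1
        assert fit.sigma2 == pytest.approx(0.04, abs=1e-12)
        assert wt.loc["Trt", "F"] == pytest.approx(4.0 / 0.04, rel=1e-12)
        assert wt.loc["Block", "F"] == pytest.approx(1.0 / 0.04, rel=1e-12)

    def test_noiseless_effects_reported_na_with_note(self):
        rows = []
        for b in ("B1", "B2"):
            for t, teff in (("T1", 0.0), ("T2", 2.0)):
                rows.append({"subject": f"{b}{t}", "Block": b, "Trt": t,
                             "y": 5.0 + teff})
        df = pd.DataFrame(rows).set_index("subject")
        table = TraitTable(df, factors=("Block", "Trt"), traits=("y",),
                           block="Block")
        fit = sg.fit_rcbd(table, sg.ModelSpec(response="y", factors=("Trt",)))
        wt = sg.wald_tests(fit).set_index("term")
        assert np.isnan(wt.loc["Trt", "F"])
        assert wt.loc["Trt", "note"] == "zero residual variance"

    @pytest.mark.parametrize("seed", range(5))
    def test_balanced_typeII_equals_classical_anova(self, seed):
        table = balanced_table(np.random.default_rng(seed))
        fit = sg.fit_rcbd(table, SPEC)
        wt = sg.wald_tests(fit).set_index("term")
        oracle, df_resid = classical_balanced_anova(table.data)
        assert fit.df_resid == df_resid
        for term, f_oracle in oracle.items():
            assert wt.loc[term, "F"] == pytest.approx(f_oracle, rel=1e-8)

    def test_unbalanced_matches_statsmodels_type2(self):
        import statsmodels.api as smapi
        import statsmodels.formula.api as smf

        table = balanced_table(np.random.default_rng(11))
        data = table.data.copy()
        data.loc[data.index[:3], "y"] = np.nan  # remove three plants
        fit = sg.fit_rcbd(
            TraitTable(data, table.factors, table.traits, table.block), SPEC
        )
        wt = sg.wald_tests(fit).set_index("term")
        sm_fit = smf.ols("y ~ C(Block) + C(Zn)*C(AMF)", data.dropna()).fit()
        an = smapi.stats.anova_lm(sm_fit, typ=2)
        pairs = [("Zn", "C(Zn)"), ("AMF", "C(AMF)"), ("Zn:AMF", "C(Zn):C(AMF)")]
        for ours, theirs in pairs:
            assert wt.loc[ours, "F"] == pytest.approx(an.loc[theirs, "F"],
                                                      rel=1e-10)

    def test_empty_cell_raises_naming_cell(self):
        table = balanced_table()
        data = table.data.copy()
        data = data[~((data["Zn"] == 40) & (data["AMF"] == "-"))]
        with pytest.raises(EstimabilityError, match="Zn=40.*AMF=-"):
            sg.fit_rcbd(TraitTable(data, table.factors, ("y",), "Block"), SPEC)

    def test_null_term_f_mean_near_one(self):
        """E[F] = ddf/(ddf-2) under the null; 200 simulated tables."""
        fs = []
        for s in range(200):
            table = balanced_table(np.random.default_rng(1000 + s))
            wt = sg.wald_tests(sg.fit_rcbd(table, SPEC)).set_index("term")
            fs.append(wt.loc["Zn", "F"])
        assert np.mean(fs) == pytest.approx(21 / 19, abs=0.15)


class TestPredictions:
    def test_balanced_closed_forms(self):
        table = balanced_table(np.random.default_rng(3))
        fit = sg.fit_rcbd(table, SPEC)
        pred = sg.predict_cells(fit)
        s = np.sqrt(fit.sigma2)
        sed = s * np.sqrt(2.0 / 4.0)  # r = 4 replicates per cell
        off = pred.sed.to_numpy()[~np.eye(8, dtype=bool)]
        np.testing.assert_allclose(off, sed, rtol=1e-10)
        lsd = st.t.ppf(0.975, fit.df_resid) * sed
        assert pred.lsd_summary == pytest.approx(lsd, rel=1e-10)
        # cell estimates are the cell means adjusted for blocks = cell means
        cells = table.data.groupby(["Zn", "AMF"], observed=True)["y"].mean()
        for _, row in pred.frame.iterrows():
            assert row["estimate"] == pytest.approx(
                cells.loc[(row["Zn"], row["AMF"])], rel=1e-10
            )

    def test_equal_cells_within_lsd(self):
        table = balanced_table(np.random.default_rng(4), sigma=1.0)
        fit = sg.fit_rcbd(table, SPEC)
        pred = sg.predict_cells(fit)
        est = pred.frame["estimate"].to_numpy()
        # same true mean everywhere: most pairwise gaps fall inside the LSD
        gaps = np.abs(est[:, None] - est[None, :])
        inside = gaps[~np.eye(8, dtype=bool)] < pred.lsd.to_numpy()[
            ~np.eye(8, dtype=bool)
        ]
        assert inside.mean() > 0.5

    def test_shift_invariance(self):
        table = balanced_table(np.random.default_rng(5))
        fit1 = sg.fit_rcbd(table, SPEC)
        shifted = table.data.copy()
        shifted["y"] = shifted["y"] + 100.0
        fit2 = sg.fit_rcbd(
            TraitTable(shifted, table.factors, table.traits, "Block"), SPEC
        )
        wt1, wt2 = sg.wald_tests(fit1), sg.wald_tests(fit2)
        np.testing.assert_allclose(wt1["F"], wt2["F"], rtol=1e-9)
        p1, p2 = sg.predict_cells(fit1), sg.predict_cells(fit2)
        np.testing.assert_allclose(
            p2.frame["estimate"], p1.frame["estimate"] + 100.0, rtol=1e-12
        )
        np.testing.assert_allclose(p2.sed, p1.sed, rtol=1e-9)

    def test_unbalanced_sed_exceeds_balanced(self):
        table = balanced_table(np.random.default_rng(6))
        fit_bal = sg.fit_rcbd(table, SPEC)
        data = table.data.copy()
        drop = data[(data["Zn"] == 0) & (data["AMF"] == "+")].index[0]
        data.loc[drop, "y"] = np.nan
        fit_unb = sg.fit_rcbd(
            TraitTable(data, table.factors, table.traits, "Block"), SPEC
        )
        p_bal, p_unb = sg.predict_cells(fit_bal), sg.predict_cells(fit_unb)
        lab = "0:+"
        # normalize by sigma to isolate the design effect
        ratio_unb = p_unb.sed.loc[lab].drop(lab) / np.sqrt(fit_unb.sigma2)
        ratio_bal = p_bal.sed.loc[lab].drop(lab) / np.sqrt(fit_bal.sigma2)
        assert (ratio_unb.to_numpy() > ratio_bal.to_numpy()).all()


class TestResidualDiagnostics:
    def test_residuals_sum_to_zero_per_block(self):
        table = balanced_table(np.random.default_rng(7))
        fit = sg.fit_rcbd(table, SPEC)
        res = pd.Series(fit.residuals, index=fit.data.index)
        sums = res.groupby(fit.data["Block"]).sum()
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)

    def test_qq_table_monotone(self):
        fit = sg.fit_rcbd(balanced_table(np.random.default_rng(8)), SPEC)
        qq = sg.residual_diagnostics(fit)["qq"]
        assert qq["theoretical"].is_monotonic_increasing
        assert qq["ordered_residual"].is_monotonic_increasing

    def test_heavy_tails_inflate_max_standardized_residual(self):
        maxes = {"gauss": [], "heavy": []}
        for s in range(40):
            rng = np.random.default_rng(s)
            t_gauss = balanced_table(rng, sigma=1.0)
            fitg = sg.fit_rcbd(t_gauss, SPEC)
            maxes["gauss"].append(
                np.abs(sg.residual_diagnostics(fitg)["rvf"]["standardized"]).max()
            )
            data = t_gauss.data.copy()
            data["y"] = 10.0 + rng.standard_t(df=2, size=len(data))
            fith = sg.fit_rcbd(
                TraitTable(data, t_gauss.factors, ("y",), "Block"), SPEC
            )
            maxes["heavy"].append(
                np.abs(sg.residual_diagnostics(fith)["rvf"]["standardized"]).max()
            )
        assert np.mean(maxes["heavy"]) > np.mean(maxes["gauss"])


class TestMultiTrait:
    def test_bookkeeping_19_traits_times_4_terms(self, trait_table):
        summary = sg.analyze_all_traits(
            trait_table, sg.ModelSpec(response="", block="Block")
        )
        assert len(summary.frame) == 19 * 4
        assert set(summary.frame["term"]) == {"Block", "Zn", "AMF", "Zn:AMF"}
        assert not summary.failures

    def test_fast_path_matches_per_trait_fits(self, trait_table):
        summary = sg.analyze_all_traits(
            trait_table, sg.ModelSpec(response="", block="Block")
        )
        for trait in ["sPSA.33", "sPSA.AGR.33_39", "sPSA.RGR.43_51"]:
            fit = sg.fit_rcbd(trait_table, sg.ModelSpec(response=trait))
            wt = sg.wald_tests(fit).set_index("term")
            sub = summary.frame[summary.frame["trait"] == trait].set_index("term")
            np.testing.assert_allclose(sub["F"], wt.loc[sub.index, "F"],
                                       rtol=1e-9)

    def test_injected_late_effects_detected_where_injected(self, trait_table):
        data = trait_table.data.copy()
        boost = (data["AMF"] == "+").astype(float)
        data["sPSA.AGR.43_51"] = data["sPSA.AGR.43_51"] + 5.0 * boost
        tt = TraitTable(data, trait_table.factors, trait_table.traits, "Block")
        summary = sg.analyze_all_traits(tt, sg.ModelSpec(response="", block="Block"))
        f = summary.frame.set_index(["trait", "term"])
        assert f.loc[("sPSA.AGR.43_51", "AMF"), "p"] < 1e-6


class TestImpliedAR1:
    def test_values(self):
        assert sg.implied_ar1_correlation(0.88, 1) == pytest.approx(0.88)
        assert sg.implied_ar1_correlation(0.88, 2) == pytest.approx(0.7744)
        assert round(sg.implied_ar1_correlation(0.88, 2), 2) == 0.77
        assert sg.implied_ar1_correlation(0.0, 7) == 0.0

    def test_validation(self):
        with pytest.raises(ParameterError):
            sg.implied_ar1_correlation(1.2, 1)
        with pytest.raises(ParameterError):
            sg.implied_ar1_correlation(0.5, 0)
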