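"""Logistic fits, RERI, joint effects, stratified and extended models."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.special import expit

from gxsep.models import (
    SingleClassError,
    compute_reri,
    extended_interaction_model,
    fit_logistic,
    interaction_model,
    joint_effects,
    main_effect_models,
    single_snp_scan,
    stratified_effects,
)
from conftest import quick_frame


def two_by_two(a, b, c, d):
    """Rows for a 2x2 table: a,b = cases/controls exposed; c,d unexposed."""
    rows = (
        [(1, 1)] * a + [(0, 1)] * b + [(1, 0)] * c + [(0, 0)] * d
    )
    return pd.DataFrame(rows, columns=["y", "x"], dtype=float)


class TestFitLogistic:
    def test_saturated_2x2_equals_log_cross_product_ratio(self):
        df = two_by_two(10, 20, 30, 40)
        fit = fit_logistic(df, "y", ["x"])
        assert fit.params["x"] == pytest.approx(math.log(10 * 40 / (20 * 30)), abs=1e-8)
        assert fit.n == 100 and fit.n_case == 40

    def test_matches_independent_optimizer(self):
        """The statsmodels solution matches a scipy minimisation of the
        hand-written negative log-likelihood to 1e-6."""
        rng = np.random.default_rng(17)
        n = 500
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.binomial(1, 0.4, n)])
        beta_true = np.array([-1.0, 0.6, -0.4])
        y = rng.random(n) < expit(X @ beta_true)
        df = pd.DataFrame({"y": y.astype(float), "x1": X[:, 1], "x2": X[:, 2]})
        fit = fit_logistic(df, "y", ["x1", "x2"])

        def nll(beta):
            lp = X @ beta
            return -np.sum(y * lp - np.logaddexp(0.0, lp))

        ref = minimize(nll, np.zeros(3), method="BFGS", tol=1e-12)
        assert np.allclose(fit.params.to_numpy(), ref.x, atol=1e-6)
        # local optimality: perturbing the solution never raises the llf
        rng2 = np.random.default_rng(1)
        for _ in range(20):
            pert = fit.params.to_numpy() + rng2.normal(scale=1e-3, size=3)
            assert -nll(pert) <= fit.llf + 1e-12

    def test_null_covariate_near_zero(self):
        rng = np.random.default_rng(24)
        n = 20_000
        noise = rng.normal(size=n)
        y = rng.random(n) < 0.2
        df = pd.DataFrame({"y": y.astype(float), "z": noise})
        fit = fit_logistic(df, "y", ["z"])
        se = math.sqrt(fit.vcov.loc["z", "z"])
        assert abs(fit.params["z"]) < 2 * se

    def test_single_class_raises(self):
        df = pd.DataFrame({"y": [1.0] * 10, "x": range(10)})
        with pytest.raises(SingleClassError):
            fit_logistic(df, "y", ["x"])

    def test_complete_case_counting(self):
        df = two_by_two(10, 20, 30, 40)
        df.loc[df.index[:7], "x"] = np.nan
        fit = fit_logistic(df, "y", ["x"])
        assert fit.n == 93 and fit.n_excluded == 7

    def test_separation_flagged(self):
        df = pd.DataFrame({"y": [0.0] * 20 + [1.0] * 20, "x": [0.0] * 20 + [1.0] * 20})
        fit = fit_logistic(df, "y", ["x"])
        assert not fit.converged


class TestReri:
    @pytest.mark.parametrize(
        "ors,expected",
        [
            ((1.01, 0.58, 1.17), 0.10),  # education x first GRS
            ((1.04, 0.89, 1.08), 0.07),  # income x first GRS
            ((1.19, 3.62, 0.90), 0.07),  # income x second GRS
        ],
    )
    def test_published_or_worked_examples(self, ors, expected):
        """RERI recomputed from printed interaction-model ORs reproduces the
        published additive-interaction estimates after 2-decimal rounding."""
        reri, _, _ = compute_reri(*(math.log(v) for v in ors))
        assert round(reri, 2) == expected

    def test_global_null(self):
        reri, _, se = compute_reri(0.0, 0.0, 0.0, np.zeros((3, 3)))
        assert reri == 0.0
        assert se == 0.0

    def test_null_gradient_structure(self):
        """At the global null only the interaction coordinate carries
        gradient: var(RERI) = var(b_int)."""
        sigma = np.diag([0.4, 0.5, 0.6])
        _, _, se = compute_reri(0.0, 0.0, 0.0, sigma)
        assert se == pytest.approx(math.sqrt(0.6))

    @given(
        st.floats(-1.5, 1.5), st.floats(-1.5, 1.5), st.floats(-1.5, 1.5)
    )
    @settings(deadline=None, max_examples=100)
    def test_reri_identity(self, bg, bs, bi):
        """RERI = OR11 − OR10 − OR01 + 1 for any coefficients."""
        reri, _, _ = compute_reri(bg, bs, bi)
        or11 = math.exp(bg + bs + bi)
        assert reri == pytest.approx(or11 - math.exp(bg) - math.exp(bs) + 1, rel=1e-12)

    def test_non_psd_vcov_rejected(self):
        sigma = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, -0.5]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            compute_reri(0.1, 0.1, 0.1, sigma)
        with pytest.raises(ValueError, match="symmetric"):
            compute_reri(0.1, 0.1, 0.1, np.arange(9.0).reshape(3, 3))

    def test_multiplicative_null_closed_form(self):
        """With b_int = 0, RERI = (OR_g − 1)(OR_s − 1)."""
        bg, bs = math.log(1.3), math.log(0.7)
        reri, _, _ = compute_reri(bg, bs, 0.0)
        assert reri == pytest.approx((1.3 - 1) * (0.7 - 1), rel=1e-12)


class TestInteractionModel:
    def test_recovers_generating_interaction(self):
        df = quick_frame(60_000, 31)
        res = interaction_model(df)
        b = math.log(res.or_interaction)
        se = math.sqrt(res.fit.vcov.iloc[-1, -1])
        assert abs(b - math.log(1.17)) < 2 * se
        assert res.or_ci[0] < res.or_interaction < res.or_ci[1]
        assert res.reri_ci[0] < res.reri < res.reri_ci[1]

    def test_null_interaction_small(self):
        df = quick_frame(60_000, 37, beta_interaction=0.0)
        res = interaction_model(df)
        se = math.sqrt(res.fit.vcov.iloc[-1, -1])
        assert abs(math.log(res.or_interaction)) < 2.5 * se

    def test_reference_recoding_equivalence(self):
        """Flipping the SEP reference maps (b_g, b_s, b_int) to
        (b_g + b_int, −b_s, −b_int); verified on refitted models."""
        df = quick_frame(8000, 41)
        base = interaction_model(df)
        flipped = df.copy()
        flipped["sep_high"] = 1.0 - flipped["sep_high"]
        alt = interaction_model(flipped)
        b, a = base.fit.params, alt.fit.params
        int_term = "grs_x_sep_high"
        assert a["grs"] == pytest.approx(b["grs"] + b[int_term], abs=1e-6)
        assert a["sep_high"] == pytest.approx(-b["sep_high"], abs=1e-6)
        assert a[int_term] == pytest.approx(-b[int_term], abs=1e-6)

    def test_rereference_reri_matches_four_cell_oracle(self):
        """With binary exposures, RERI under either reference equals the
        value from the saturated four-cell probability oracle."""
        rng = np.random.default_rng(53)
        n = 40_000
        g = rng.binomial(1, 0.4, n).astype(float)
        s = rng.binomial(1, 0.5, n).astype(float)
        p = expit(-2.5 + 0.4 * g - 0.5 * s + 0.6 * g * s)
        y = (rng.random(n) < p).astype(float)
        df = pd.DataFrame({"mgus": y, "grs": g, "sep_high": s})
        res = interaction_model(df, covariates=())
        # oracle: odds ratios straight from the four cell probabilities
        cells = {
            (gi, si): y[(g == gi) & (s == si)].mean()
            for gi in (0, 1) for si in (0, 1)
        }
        def odds(p_):
            return p_ / (1 - p_)
        or10 = odds(cells[1, 0]) / odds(cells[0, 0])
        or01 = odds(cells[0, 1]) / odds(cells[0, 0])
        or11 = odds(cells[1, 1]) / odds(cells[0, 0])
        assert res.reri == pytest.approx(or11 - or10 - or01 + 1, abs=1e-9)
        # re-referenced RERI agrees with the oracle referenced to (0, 1)
        with pytest.warns(UserWarning, match="re-referencing"):
            reref = interaction_model(df, covariates=(), rereference=True)
        or10_b = odds(cells[1, 1]) / odds(cells[0, 1])
        or01_b = odds(cells[0, 0]) / odds(cells[0, 1])
        or11_b = odds(cells[1, 0]) / odds(cells[0, 1])
        assert reref.reri == pytest.approx(or11_b - or10_b - or01_b + 1, abs=1e-9)

    def test_grs_increment_scaling(self):
        df = quick_frame(8000, 43)
        per1 = interaction_model(df, grs_increment=1.0)
        per2 = interaction_model(df, grs_increment=2.0)
        assert per2.or_interaction == pytest.approx(per1.or_interaction**2, rel=1e-9)

    def test_bootstrap_ci_close_to_delta(self):
        df = quick_frame(20_000, 47)
        delta = interaction_model(df, ci_method="delta")
        boot = interaction_model(df, ci_method="bootstrap", n_boot=120, seed=7)
        assert boot.reri == pytest.approx(delta.reri, abs=1e-12)
        width = delta.reri_ci[1] - delta.reri_ci[0]
        assert abs(boot.reri_ci[0] - delta.reri_ci[0]) < 0.5 * width
        assert abs(boot.reri_ci[1] - delta.reri_ci[1]) < 0.5 * width

    def test_bootstrap_requires_seed(self):
        df = quick_frame(2000, 49)
        with pytest.raises(ValueError, match="seed"):
            interaction_model(df, ci_method="bootstrap")


class TestAnalysisTables:
    def test_main_effects_bookkeeping(self, analysis_frame):
        tab = main_effect_models(
            analysis_frame, exposures=("grs", "education_high", "income_high")
        )
        # complete-case n per model equals the non-missing row count of
        # exactly that model's variables
        for term in tab.index:
            expected = analysis_frame[["mgus", "age", "male", term]].dropna().shape[0]
            assert tab.loc[term, "n"] + tab.loc[term, "n_excluded"] == len(analysis_frame)
            assert tab.loc[term, "n"] == expected
        assert (tab["ci_low"] < tab["or"]).all() and (tab["or"] < tab["ci_high"]).all()

    def test_stratified_single_stratum_reduces_to_plain_fit(self, analysis_frame):
        df = analysis_frame.copy()
        df["one"] = "all"
        strat = stratified_effects(df, strata="one")
        fit = fit_logistic(df, "mgus", ["age", "male", "grs"])
        assert strat.loc["all", "or"] == pytest.approx(
            float(np.exp(fit.params["grs"])), rel=1e-9
        )
        assert strat.loc["all", "n"] == fit.n

    def test_stratified_interaction_ordering(self):
        """A strong positive interaction yields a larger GRS OR in the high-
        SEP stratum."""
        df = quick_frame(60_000, 59, beta_interaction=math.log(1.5))
        df["sep_cat"] = pd.Categorical(
            np.where(df["sep_high"] == 1.0, "high", "low"),
            categories=["low", "high"], ordered=True,
        )
        strat = stratified_effects(df, strata="sep_cat")
        assert strat.loc["high", "or"] > strat.loc["low", "or"]

    def test_stratified_single_class_stratum_flagged(self):
        df = quick_frame(4000, 61)
        df.loc[df["sep_high"] == 1.0, "mgus"] = 0
        df["sep_cat"] = np.where(df["sep_high"] == 1.0, "high", "low")
        strat = stratified_effects(df, strata="sep_cat")
        assert not strat.loc["high", "estimable"]
        assert strat.loc["low", "estimable"]

    def test_joint_effects_reference_and_partition(self, analysis_frame):
        tab = joint_effects(analysis_frame, sep="education_cat4")
        ref = tab[tab["is_reference"]]
        assert len(ref) == 1 and ref["or"].iloc[0] == 1.0
        assert ref["tertile"].iloc[0] == "lower" and ref["sep"].iloc[0] == "<=10"
        # cells partition the analysed sample
        valid = analysis_frame.dropna(subset=["grs_tertile", "education_cat4", "mgus"])
        assert tab["n"].sum() == len(valid)
        assert tab["n_case"].sum() == valid["mgus"].sum()

    def test_joint_effects_collapsed_sep_equals_tertile_factor_fit(self, analysis_frame):
        df = analysis_frame.copy()
        df["sep_one"] = pd.Categorical(["only"] * len(df))
        tab = joint_effects(df, sep="sep_one")
        dummies = pd.get_dummies(df["grs_tertile"], prefix="t").astype(float)
        work = pd.concat([df[["mgus", "age", "male"]], dummies], axis=1)
        fit = fit_logistic(work, "mgus", ["age", "male", "t_middle", "t_highest"])
        got = tab.set_index("tertile")["or"]
        assert got["middle"] == pytest.approx(
            float(np.exp(fit.params["t_middle"])), rel=1e-6
        )
        assert got["highest"] == pytest.approx(
            float(np.exp(fit.params["t_highest"])), rel=1e-6
        )

    def test_joint_effects_expected_ordering_under_positive_effects(self):
        """With positive GRS, SEP and interaction effects the (highest
        tertile, high SEP) cell has the largest OR at large n."""
        df = quick_frame(
            100_000, 67,
            beta_grs=math.log(1.15), beta_sep=math.log(1.3),
            beta_interaction=math.log(1.1),
        )
        from gxsep.grs import tertiles

        df["grs_tertile"] = tertiles(df["grs"])
        df["sep_cat"] = pd.Categorical(
            np.where(df["sep_high"] == 1.0, "high", "low"),
            categories=["low", "high"], ordered=True,
        )
        tab = joint_effects(df, sep="sep_cat")
        top = tab.loc[(tab["tertile"] == "highest") & (tab["sep"] == "high"), "or"]
        assert top.iloc[0] == tab["or"].max()

    def test_joint_effects_empty_cell_flagged(self, analysis_frame):
        df = analysis_frame.copy()
        drop = (df["grs_tertile"] == "highest") & (df["education_cat4"] == ">=18")
        df = df[~drop]
        with pytest.warns(UserWarning, match="empty"):
            tab = joint_effects(df, sep="education_cat4")
        cell = tab[(tab["tertile"] == "highest") & (tab["sep"] == ">=18")]
        assert not cell["estimable"].iloc[0] and cell["n"].iloc[0] == 0

    def test_extended_model_irrelevant_rf_keeps_estimate(self, analysis_frame):
        df = analysis_frame.copy()
        rng = np.random.default_rng(71)
        df["noise_rf"] = rng.binomial(1, 0.3, len(df)).astype(float)
        base = interaction_model(df, sep="education_high")
        ext = extended_interaction_model(df, "noise_rf", sep="education_high")
        assert math.log(ext.or_interaction) == pytest.approx(
            math.log(base.or_interaction), abs=0.05
        )
        assert ext.n == base.n

    def test_extended_model_mediating_rf_attenuates(self):
        """When the interaction truly runs through a risk factor correlated
        with SEP, adding its terms attenuates the GRS×SEP estimate."""
        rng = np.random.default_rng(73)
        n = 120_000
        grs = rng.binomial(2, 0.3, n) + rng.binomial(2, 0.3, n).astype(float)
        sep = rng.binomial(1, 0.4, n).astype(float)
        # risk factor strongly SEP-patterned; interaction acts via RF only
        rf = (rng.random(n) < np.where(sep == 1.0, 0.75, 0.2)).astype(float)
        p = expit(-3.2 + 0.02 * grs + 0.1 * sep + 0.25 * grs * rf)
        df = pd.DataFrame(
            {
                "mgus": (rng.random(n) < p).astype(float),
                "grs": grs, "sep_high": sep, "rf": rf,
                "age": 0.0, "male": 0.0,
            }
        )
        base = interaction_model(df, covariates=())
        ext = extended_interaction_model(df, "rf", covariates=())
        assert abs(math.log(ext.or_interaction)) < abs(math.log(base.or_interaction))

    def test_extended_model_complete_case_n_tracks_rf(self, analysis_frame):
        df = analysis_frame.copy()
        rng = np.random.default_rng(79)
        rf = rng.binomial(1, 0.3, len(df)).astype(float)
        rf[rng.random(len(df)) < 0.05] = np.nan
        df["patchy_rf"] = rf
        ext = extended_interaction_model(df, "patchy_rf", sep="education_high")
        expected = df[
            ["mgus", "age", "male", "grs", "education_high", "patchy_rf"]
        ].dropna()
        assert ext.n == len(expected)


class TestSingleSnpScan:
    def test_single_snp_panel_reduces_to_interaction_model(self, default_cohort, analysis_frame):
        df = analysis_frame.join(default_cohort.genotypes[["snp03"]])
        scan = single_snp_scan(df, ["snp03"], sep="education_high")
        direct = interaction_model(df, grs="snp03", sep="education_high")
        assert scan.loc["snp03", "or_interaction"] == pytest.approx(
            direct.or_interaction, rel=1e-9
        )
        assert scan.loc["snp03", "reri"] == pytest.approx(direct.reri, rel=1e-9)

    def test_monomorphic_snp_skipped(self, default_cohort, analysis_frame):
        df = analysis_frame.join(default_cohort.genotypes[["snp03"]])
        df["mono"] = 0.0
        scan = single_snp_scan(df, ["snp03", "mono"], sep="education_high")
        assert not scan.loc["mono", "estimable"]
        assert np.isnan(scan.loc["mono", "or_interaction"])
        assert scan.loc["snp03", "estimable"]

    def test_consistency_counts_with_shared_effect(self):
        """If every SNP carries the same positive interaction, consistency
        with the GRS-level direction is (near-)total at large n."""
        rng = np.random.default_rng(83)
        n = 150_000
        snps = {f"s{i}": rng.binomial(2, 0.3, n).astype(float) for i in range(4)}
        sep = rng.binomial(1, 0.5, n).astype(float)
        grs = sum(snps.values())
        p = expit(-3.4 + 0.18 * grs * sep)
        df = pd.DataFrame(
            {"mgus": (rng.random(n) < p).astype(float), "sep_high": sep, **snps}
        )
        scan = single_snp_scan(df, list(snps), covariates=(), reference_sign=1.0)
        assert scan.attrs["n_consistent_mult"] == 4
        assert scan.attrs["n_consistent_add"] == 4
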