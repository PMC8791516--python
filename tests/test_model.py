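"""Mixed-logit estimation: oracle equivalence, selection, OR bookkeeping, GOF."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from capnet.model import (
    ConvergenceError,
    MixedLogit,
    MixedMultinomialLogit,
    SingularDesignError,
    _ResultsBase,
    constrained_comparison,
    hosmer_lemeshow,
    scale_odds_ratio,
    stepwise_select,
)
from capnet.simulate import simulate_logistic_cohort

FIXED = ["vsd", "female", "htn", "hld"]


@pytest.fixture(scope="module")
def flat_df():
    """Cohort with no subject clustering (zero random-effect variance)."""
    return simulate_logistic_cohort(n_subjects=330, subject_sd=0.0, seed=3)


@pytest.fixture(scope="module")
def clustered_df():
    return simulate_logistic_cohort(n_subjects=330, subject_sd=0.7, seed=11)


class TestPlainLogisticOracle:
    def test_matches_statsmodels_irls(self, flat_df):
        res = MixedLogit.from_dataframe(flat_df, "y", FIXED, subject=None).fit()
        X = sm.add_constant(flat_df[FIXED].astype(float))
        oracle = sm.Logit(flat_df["y"], X).fit(disp=0)
        np.testing.assert_allclose(res.params.to_numpy(), oracle.params.to_numpy(),
                                   atol=1e-6)
        np.testing.assert_allclose(res.bse.to_numpy(), oracle.bse.to_numpy(),
                                   atol=1e-6)
        assert res.llf == pytest.approx(oracle.llf, abs=1e-6)

    def test_zero_variance_limit_equals_plain_fit(self, flat_df):
        mixed0 = MixedLogit.from_dataframe(flat_df, "y", FIXED).fit(fix_re_sd=0.0)
        X = sm.add_constant(flat_df[FIXED].astype(float))
        oracle = sm.Logit(flat_df["y"], X).fit(disp=0)
        np.testing.assert_allclose(mixed0.params.to_numpy(),
                                   oracle.params.to_numpy(), atol=1e-6)

    def test_multinomial_matches_mnlogit(self):
        rng = np.random.default_rng(7)
        n = 600
        x = rng.normal(size=n)
        z = rng.binomial(1, 0.4, size=n)
        eta1 = -0.3 + 1.1 * x + 0.5 * z
        eta2 = 0.2 - 0.8 * x + 0.9 * z
        denom = 1 + np.exp(eta1) + np.exp(eta2)
        u = rng.random(n)
        p1, p2 = np.exp(eta1) / denom, np.exp(eta2) / denom
        y = np.where(u < p1, 1, np.where(u < p1 + p2, 2, 0))
        df = pd.DataFrame({"y": y, "x": x, "z": z})
        res = MixedMultinomialLogit.from_dataframe(
            df, "y", ["x", "z"], subject=None, levels=[0, 1, 2]
        ).fit()
        oracle = sm.MNLogit(y, sm.add_constant(df[["x", "z"]].astype(float))).fit(disp=0)
        np.testing.assert_allclose(
            res.params.to_numpy(), oracle.params.to_numpy().T.ravel(), atol=1e-6
        )


class TestDegenerateDesigns:
    def test_complete_separation_raises(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        df = pd.DataFrame({"y": (x > 0).astype(int), "x": x})
        with pytest.raises(ConvergenceError):
            MixedLogit.from_dataframe(df, "y", ["x"], subject=None).fit()

    def test_constant_predictor_raises(self, flat_df):
        df = flat_df.assign(flat=1.0)
        with pytest.raises(SingularDesignError):
            MixedLogit.from_dataframe(df, "y", FIXED + ["flat"], subject=None).fit()

    def test_collinear_predictors_raise(self, flat_df):
        df = flat_df.assign(vsd2=flat_df["vsd"] * 2.0)
        with pytest.raises(SingularDesignError):
            MixedLogit.from_dataframe(df, "y", FIXED + ["vsd2"], subject=None).fit()

    def test_single_level_outcome_raises(self, flat_df):
        df = flat_df.assign(y=1)
        with pytest.raises(ValueError):
            MixedLogit.from_dataframe(df, "y", FIXED)


class TestMixedFit:
    def test_nesting_never_harms_likelihood(self, clustered_df):
        full = MixedLogit.from_dataframe(clustered_df, "y", FIXED).fit()
        reduced = MixedLogit.from_dataframe(clustered_df, "y", FIXED[1:]).fit()
        assert full.llf >= reduced.llf - 1e-6

    def test_null_effect_ci_covers_one(self):
        df = simulate_logistic_cohort(
            n_subjects=330, beta={"vsd": 0.0, "htn": 0.8}, subject_sd=0.6, seed=17
        )
        res = MixedLogit.from_dataframe(df, "y", FIXED).fit()
        ci = res.conf_int().loc["vsd"] * 0.001
        assert ci["lower"] <= 0.0 <= ci["upper"]
        assert math.exp(res.params["vsd"] * 0.001) == pytest.approx(1.0, abs=0.05)

    def test_reporting_scale_is_power_of_unit_or(self, clustered_df):
        res = MixedLogit.from_dataframe(clustered_df, "y", FIXED).fit()
        or_unit = math.exp(res.params["vsd"])
        or_small = math.exp(res.params["vsd"] * 0.001)
        assert or_small == pytest.approx(or_unit**0.001, rel=1e-12)


@pytest.fixture(scope="module")
def cohort():
    from capnet.simulate import CohortConfig, generate_cohort

    df = generate_cohort(CohortConfig.cohort1(seed=8))
    df["male"] = (df["sex"] == "M").astype(int)
    return df


class TestConstrainedComparison:
    def test_any_vs_control_preserves_rows(self, cohort):
        res = constrained_comparison(cohort, "any_vs_control", ["vsd", "male"])
        assert res.nobs == len(cohort)

    def test_matches_manual_recode(self, cohort):
        res = constrained_comparison(cohort, "referable_vs_mild", ["vsd", "htn"])
        manual = cohort[cohort.dr_class.isin(["mild", "referable"])].copy()
        manual["_y"] = (manual.dr_class == "referable").astype(int)
        oracle = MixedLogit.from_dataframe(manual, "_y", ["vsd", "htn"]).fit()
        np.testing.assert_allclose(res.params.to_numpy(), oracle.params.to_numpy(),
                                   rtol=1e-8)

    def test_unknown_contrast(self, cohort):
        with pytest.raises(ValueError, match="contrast"):
            constrained_comparison(cohort, "severe_vs_mild", ["vsd"])


class _StubResults(_ResultsBase):
    """Results shell carrying a prescribed coefficient and SE (OR arithmetic)."""

    def __init__(self, params, bse):
        self.params = params
        self.bse = bse


def stub_from_or(or_point, or_lo, or_hi, delta=0.001, name="vsd"):
    """Results whose reporting-scale OR and ~CI equal the given values."""
    z = stats.norm.ppf(0.975)
    params = pd.Series({name: math.log(or_point) / delta})
    bse = pd.Series({name: (math.log(or_hi) - math.log(or_lo)) / (2 * z * delta)})
    return _StubResults(params, bse)


class TestScaleOddsRatio:
    def test_published_or_to_percent_decrease(self):
        # OR 0.85 per +0.001 VSD <=> odds decrease 15% per increase and
        # increase 18% per 0.001-unit decrease
        fit = stub_from_or(0.85, 0.82, 0.88)
        inc = scale_odds_ratio(fit, "vsd", 0.001, "increase")
        assert inc["percent_rounded"] == -15
        dec = scale_odds_ratio(fit, "vsd", 0.001, "decrease")
        assert dec["percent_rounded"] == 18

    def test_ci_transforms_monotonically(self):
        fit = stub_from_or(0.85, 0.82, 0.88)
        dec = scale_odds_ratio(fit, "vsd", 0.001, "decrease")
        assert dec["percent_ci_rounded"] == (14, 22)
        inc = scale_odds_ratio(fit, "vsd", 0.001, "increase")
        assert inc["percent_ci_rounded"] == (-18, -12)

    def test_zero_effect(self):
        fit = stub_from_or(1.0, 0.95, 1.0 / 0.95)
        for direction in ("increase", "decrease"):
            assert scale_odds_ratio(fit, "vsd", 0.001, direction)["percent"] == pytest.approx(0.0, abs=1e-9)

    def test_unknown_variable(self):
        fit = stub_from_or(0.85, 0.82, 0.88)
        with pytest.raises(KeyError):
            scale_odds_ratio(fit, "vdi", 0.01, "increase")


class TestHosmerLemeshow:
    def test_matches_brute_force_deciles(self):
        rng = np.random.default_rng(5)
        probs = rng.uniform(0.05, 0.95, size=50)
        y = rng.binomial(1, probs)
        out = hosmer_lemeshow(probs, y, g=10)
        order = np.argsort(probs, kind="stable")
        stat = 0.0
        for k in range(10):
            idx = order[5 * k:5 * (k + 1)]
            pi = probs[idx].mean()
            stat += (y[idx].sum() - 5 * pi) ** 2 / (5 * pi * (1 - pi))
        assert out["statistic"] == pytest.approx(stat, rel=1e-12)
        assert out["df"] == 8

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow([0.5, 0.6], [0, 1], g=2)

    def test_null_distribution_uniform(self):
        # well-specified model at large n: HL p-values ~ U(0,1) over reps
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(200):
            x = rng.normal(size=600)
            p = expit(-0.4 + 0.9 * x)
            y = rng.binomial(1, p)
            df = pd.DataFrame({"y": y, "x": x})
            fit = MixedLogit.from_dataframe(df, "y", ["x"], subject=None).fit()
            pvals.append(hosmer_lemeshow(fit.fittedvalues, y)["p_value"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestStepwise:
    def test_strong_effects_all_retained(self):
        df = simulate_logistic_cohort(
            n_subjects=500,
            beta={"vsd": math.log(0.8) / 0.001, "female": 1.0, "htn": 1.0, "hld": 1.0},
            subject_sd=0.0,
            seed=2,
        )
        kept = stepwise_select(df, FIXED, outcome="y", subject=None)
        assert kept == FIXED

    def test_noise_covariate_usually_dropped(self):
        drops = 0
        n_rep = 50
        for rep in range(n_rep):
            df = simulate_logistic_cohort(
                n_subjects=300,
                beta={"vsd": math.log(0.8) / 0.001, "htn": 1.0},
                subject_sd=0.0,
                seed=1000 + rep,
            )
            rng = np.random.default_rng(rep)
            df["noise"] = rng.normal(size=len(df))
            kept = stepwise_select(df, ["vsd", "htn", "noise"], outcome="y", subject=None)
            drops += "noise" not in kept
        assert drops >= 0.9 * n_rep

    def test_fixed_point_property_three_candidates(self):
        # the returned set is a fixed point of the rule: every retained
        # variable significant, every excluded one non-significant on re-entry
        df = simulate_logistic_cohort(
            n_subjects=250,
            beta={"vsd": math.log(0.85) / 0.001, "female": 0.0, "htn": 0.7},
            subject_sd=0.0,
            seed=4,
        )
        cands = ["vsd", "female", "htn"]
        kept = stepwise_select(df, cands, outcome="y", subject=None)

        def pval(cols, var):
            res = MixedLogit.from_dataframe(df, "y", cols, subject=None).fit()
            return res.pvalues[var]

        for var in kept:
            assert pval(kept, var) < 0.05
        for var in set(cands) - set(kept):
            assert pval(kept + [var], var) >= 0.05
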