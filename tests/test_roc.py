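"""ROC/AUC machinery: Mann-Whitney identity, DeLong contrasts, CV, cutoffs."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from capnet.model import MixedLogit
from capnet.roc import (
    _subject_folds,
    compare_auc,
    external_validate,
    kfold_cv_auc,
    optimal_cutoff,
    roc_auc,
    sens_spec_at,
)
from capnet.simulate import simulate_logistic_cohort


def random_fixture(seed, n=40, ties=False):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=n)
    if ties:
        scores = np.round(scores, 1)
    labels = rng.binomial(1, 0.5, size=n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    return scores, labels


class TestRocAuc:
    @pytest.mark.parametrize("seed,ties", [(0, False), (1, True), (2, True), (3, False)])
    def test_equals_mann_whitney_exactly(self, seed, ties):
        scores, labels = random_fixture(seed, ties=ties)
        r = roc_auc(scores, labels)
        n1, n0 = labels.sum(), (1 - labels).sum()
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert r.auc == pytest.approx(u / (n1 * n0), rel=1e-12)
        assert r.auc == pytest.approx(roc_auc_score(labels, scores), rel=1e-12)

    def test_curve_equals_trapezoid_auc(self):
        scores, labels = random_fixture(4, ties=True)
        r = roc_auc(scores, labels)
        trap = -np.trapezoid(r.sensitivity, 1 - r.specificity)
        assert abs(abs(trap) - r.auc) < 1e-12

    def test_perfect_separation(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10), np.ones(10)]
        assert roc_auc(scores, labels).auc == 1.0

    def test_uninformative_scores_near_half(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=10000)
        labels = rng.binomial(1, 0.5, size=10000)
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_two_gaussian_closed_form(self):
        rng = np.random.default_rng(9)
        mu, s0, s1 = 1.2, 1.0, 1.5
        neg = rng.normal(0, s0, size=4000)
        pos = rng.normal(mu, s1, size=4000)
        expected = stats.norm.cdf(mu / math.hypot(s0, s1))
        auc = roc_auc(np.r_[neg, pos], np.r_[np.zeros(4000), np.ones(4000)]).auc
        assert auc == pytest.approx(expected, abs=0.015)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


def brute_force_delong(sa, sb, labels):
    """Placement-value covariance computed with explicit double loops."""
    sa, sb, labels = map(np.asarray, (sa, sb, labels))
    pos, neg = np.where(labels == 1)[0], np.where(labels == 0)[0]

    def placements(s):
        v10 = np.array([
            np.mean([(s[i] > s[j]) + 0.5 * (s[i] == s[j]) for j in neg]) for i in pos
        ])
        v01 = np.array([
            np.mean([(s[i] > s[j]) + 0.5 * (s[i] == s[j]) for i in pos]) for j in neg
        ])
        return v10, v01

    va10, va01 = placements(sa)
    vb10, vb01 = placements(sb)
    m, n = len(pos), len(neg)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    S = s10 / m + s01 / n
    return va10.mean(), vb10.mean(), S[0, 0] + S[1, 1] - 2 * S[0, 1]


class TestCompareAuc:
    def test_identical_scores_p_one(self):
        scores, labels = random_fixture(5)
        c = compare_auc(scores, scores.copy(), labels)
        assert c.difference == 0.0 and c.p_value == 1.0

    def test_matches_brute_force_on_small_fixture(self):
        rng = np.random.default_rng(6)
        labels = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1, 0])
        sa = rng.normal(size=12)
        sb = np.round(sa + rng.normal(scale=0.5, size=12), 1)
        c = compare_auc(sa, sb, labels)
        auc_a, auc_b, var = brute_force_delong(sa, sb, labels)
        assert c.auc_a == pytest.approx(auc_a, rel=1e-12)
        assert c.auc_b == pytest.approx(auc_b, rel=1e-12)
        assert c.variance == pytest.approx(var, rel=1e-10)
        assert c.chi_square == pytest.approx((auc_a - auc_b) ** 2 / var, rel=1e-9)

    def test_variance_nonnegative_across_fixtures(self):
        for seed in range(25):
            sa, labels = random_fixture(seed, n=30, ties=seed % 2)
            sb, _ = random_fixture(seed + 100, n=30)
            assert compare_auc(sa, sb, labels).variance >= 0.0

    def test_power_against_useless_competitor(self):
        rng = np.random.default_rng(13)
        rejections = 0
        for _ in range(200):
            labels = rng.binomial(1, 0.5, size=500)
            informative = labels * 1.2 + rng.normal(size=500)
            useless = rng.normal(size=500)
            if compare_auc(informative, useless, labels).p_value < 0.05:
                rejections += 1
        assert rejections / 200 > 0.5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_auc([1, 2, 3], [1, 2], [1, 0, 1])


def _binary_builder(df):
    return df, df["y"].to_numpy()


class TestKfoldCv:
    def test_perfectly_separable_data(self):
        rng = np.random.default_rng(3)
        n = 120
        x = rng.normal(size=n)
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "y": (x > 0).astype(int),
            "x2": np.where(x > 0, x + 5.0, x - 5.0),
        })
        cv = kfold_cv_auc(df, _binary_builder, ["x2"], k=5, seed=0,
                          fit_kw={"fix_re_sd": 0.0})
        assert cv.mean_auc == 1.0

    def test_equals_manual_loop_oracle(self):
        df = simulate_logistic_cohort(n_subjects=40, subject_sd=0.4, seed=19)
        fixed = ["vsd", "htn"]
        cv = kfold_cv_auc(df, _binary_builder, fixed, k=4, seed=7,
                          fit_kw={"fix_re_sd": 0.0})
        # manual loop with the same fold assignment, statsmodels fits
        import statsmodels.api as sm

        y = df["y"].to_numpy()
        folds = _subject_folds(df.reset_index(drop=True), 4, 7, "subject_id", y)
        manual = []
        for f in range(4):
            test = folds == f
            if y[test].min() == y[test].max():
                continue
            Xtr = sm.add_constant(df.loc[~test, fixed].astype(float))
            fit = sm.Logit(y[~test], Xtr).fit(disp=0)
            Xte = sm.add_constant(df.loc[test, fixed].astype(float), has_constant="add")
            lp = Xte.to_numpy() @ fit.params.to_numpy()
            manual.append(roc_auc(lp, y[test]).auc)
        assert cv.fold_aucs == pytest.approx(manual, abs=1e-9)

    def test_subjects_never_split_across_train_and_test(self):
        df = simulate_logistic_cohort(n_subjects=60, subject_sd=0.4, seed=23)
        folds = _subject_folds(df.reset_index(drop=True), 5, 1, "subject_id",
                               df["y"].to_numpy())
        per_subject = pd.Series(folds).groupby(df["subject_id"].to_numpy()).nunique()
        assert (per_subject == 1).all()

    def test_k_floor(self):
        df = simulate_logistic_cohort(n_subjects=30, seed=0)
        with pytest.raises(ValueError):
            kfold_cv_auc(df, _binary_builder, ["vsd"], k=1, seed=0)

    def test_cv_auc_not_above_resubstitution_on_average(self):
        # optimism: held-out discrimination <= apparent discrimination
        gaps = []
        for rep in range(20):
            df = simulate_logistic_cohort(n_subjects=80, subject_sd=0.3,
                                          seed=3000 + rep)
            model = MixedLogit.from_dataframe(df, "y", ["vsd", "htn"])
            fit = model.fit(fix_re_sd=0.0)
            apparent = roc_auc(fit.predict_linear(df), df["y"]).auc
            cv = kfold_cv_auc(df, _binary_builder, ["vsd", "htn"], k=5,
                              seed=rep, fit_kw={"fix_re_sd": 0.0})
            gaps.append(apparent - cv.mean_auc)
        assert np.mean(gaps) > 0.0


class TestExternalValidation:
    def test_same_process_cohort_transports(self):
        train = simulate_logistic_cohort(n_subjects=400, subject_sd=0.5, seed=31)
        test = simulate_logistic_cohort(n_subjects=400, subject_sd=0.5, seed=32)
        fit = MixedLogit.from_dataframe(train, "y", ["vsd", "htn"]).fit()
        internal = roc_auc(fit.predict_linear(train), train["y"])
        external = external_validate(fit, test, test["y"])
        assert internal.auc_ci[0] - 0.03 <= external.auc <= internal.auc_ci[1] + 0.03

    def test_uninformative_covariates_near_chance(self):
        rng = np.random.default_rng(33)
        train = simulate_logistic_cohort(n_subjects=300, subject_sd=0.3, seed=34)
        fit = MixedLogit.from_dataframe(train, "y", ["htn", "hld"]).fit()
        test = train.copy()
        test["y"] = rng.binomial(1, 0.5, size=len(test))  # outcome detached
        external = external_validate(fit, test, test["y"])
        assert 0.35 <= external.auc <= 0.65

    def test_missing_variable_named(self):
        train = simulate_logistic_cohort(n_subjects=100, seed=35)
        fit = MixedLogit.from_dataframe(train, "y", ["vsd", "htn"]).fit()
        with pytest.raises(KeyError, match="vsd"):
            external_validate(fit, train.drop(columns=["vsd"]), train["y"])

    def test_empty_cohort(self):
        train = simulate_logistic_cohort(n_subjects=100, seed=36)
        fit = MixedLogit.from_dataframe(train, "y", ["vsd"]).fit()
        with pytest.raises(ValueError):
            external_validate(fit, train.iloc[:0], [])


class TestOptimalCutoff:
    def test_separated_clusters_rate_one(self):
        vals = np.r_[np.random.default_rng(0).normal(0.13, 0.002, 20),
                     np.random.default_rng(1).normal(0.155, 0.002, 20)]
        labels = np.r_[np.ones(20), np.zeros(20)]
        c = optimal_cutoff(vals, labels, "below_positive")
        assert c.correct_classification_rate == 1.0
        assert 0.14 < c.threshold < 0.15

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(21)
        vals = rng.normal(size=20)
        labels = (vals + rng.normal(scale=1.2, size=20) > 0).astype(int)
        c = optimal_cutoff(vals, labels, "above_positive")
        uniq = np.unique(vals)
        best = max(
            ((vals > t) == (labels == 1)).mean()
            for t in (uniq[:-1] + uniq[1:]) / 2
        )
        assert c.correct_classification_rate == pytest.approx(best, rel=1e-12)
        got = ((vals > c.threshold) == (labels == 1)).mean()
        assert got == pytest.approx(best, rel=1e-12)

    def test_label_and_direction_flip_symmetry(self):
        rng = np.random.default_rng(22)
        vals = rng.normal(size=25)
        labels = rng.binomial(1, 0.5, size=25)
        labels[0], labels[1] = 0, 1
        a = optimal_cutoff(vals, labels, "below_positive")
        b = optimal_cutoff(vals, 1 - labels, "above_positive")
        assert a.threshold == b.threshold
        assert a.correct_classification_rate == b.correct_classification_rate

    def test_rate_at_least_prevalence(self):
        for seed in range(10):
            vals, labels = random_fixture(seed, n=30)
            c = optimal_cutoff(vals, labels, "above_positive")
            prev = max(labels.mean(), 1 - labels.mean())
            assert c.correct_classification_rate >= prev - 1e-12

    def test_constant_values_error(self):
        with pytest.raises(ValueError):
            optimal_cutoff([1.0] * 5, [0, 1, 0, 1, 0], "below_positive")


class TestSensSpec:
    def test_perfect_classifier(self):
        scores = np.r_[np.zeros(5), np.ones(5)]
        labels = scores.astype(int)
        assert sens_spec_at(scores, labels) == (1.0, 1.0)

    def test_threshold_at_minus_infinity(self):
        scores, labels = random_fixture(7)
        sens, spec = sens_spec_at(scores, labels, rule="threshold",
                                  threshold=-np.inf)
        assert (sens, spec) == (1.0, 0.0)

    def test_matches_manual_confusion_table(self):
        scores = np.array([0.1, 0.9, 0.4, 0.8, 0.3, 0.7, 0.2, 0.6, 0.5, 0.95])
        labels = np.array([0, 1, 0, 1, 0, 1, 0, 0, 1, 1])
        sens, spec = sens_spec_at(scores, labels, rule="threshold", threshold=0.5)
        # by hand: scores >= 0.5 -> predictions for the 10 rows
        pred = scores >= 0.5
        tp = ((pred == 1) & (labels == 1)).sum()
        tn = ((pred == 0) & (labels == 0)).sum()
        assert sens == tp / labels.sum()
        assert spec == tn / (1 - labels).sum()
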