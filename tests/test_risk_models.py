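"""Logistic propensity models, C statistic, LR tests, deciles, splits."""

import math

import numpy as np
import pandas as pd
import pytest

from nhsi.risk_models import (
    ModelError,
    PropensityModel,
    c_statistic,
    fit_logistic,
    lr_chi_square,
    percent_improvement,
    propensity_deciles,
    run_model_suite,
    split_train_validation,
)

from _oracles import all_pairs_concordance


def _expand_2x2(a, b, c, d):
    """Cells: (x=1,y=1)=a, (x=1,y=0)=b, (x=0,y=1)=c, (x=0,y=0)=d."""
    x = [1] * (a + b) + [0] * (c + d)
    y = [1] * a + [0] * b + [1] * c + [0] * d
    return np.array(x, float), np.array(y, float)


class TestFitLogistic:
    def test_slope_equals_closed_form_log_odds_ratio_on_2x2(self):
        # printed gender-by-outcome cells: male 28 PrI / 329 none,
        # female 61 PrI / 597 none
        x, y = _expand_2x2(28, 329, 61, 597)
        fit = fit_logistic(y, x[:, None], names=["male"])
        expected = math.log((28 * 597) / (61 * 329))
        assert fit.coef_[0] == pytest.approx(expected, abs=1e-8)
        assert fit.odds_ratios_[0] == pytest.approx(math.exp(expected), rel=1e-8)

    def test_independent_predictor_gives_near_zero_slope(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=2000)
        y = rng.random(2000) < 0.2
        fit = fit_logistic(y.astype(int), x[:, None])
        z = fit.coef_[0] / fit.se_[0]
        assert abs(z) < 3.0

    def test_parameter_recovery_on_simulated_cohort(self):
        # n=5000 draws from a known logistic model; estimates within 3 SEs
        rng = np.random.default_rng(5)
        n = 5000
        X = rng.normal(size=(n, 3))
        beta = np.array([0.8, -0.5, 0.3])
        p = 1 / (1 + np.exp(-(-2.0 + X @ beta)))
        y = (rng.random(n) < p).astype(int)
        fit = fit_logistic(y, X)
        for est, se, true in zip(fit.coef_, fit.se_, beta):
            assert abs(est - true) < 3 * se
        assert abs(fit.intercept_ - (-2.0)) < 3 * fit.intercept_se_

    def test_or_ci_consistent_with_coefficients(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(400, 2))
        y = (rng.random(400) < 1 / (1 + np.exp(-(X[:, 0] - 1)))).astype(int)
        fit = fit_logistic(y, X)
        np.testing.assert_allclose(fit.odds_ratios_, np.exp(fit.coef_))
        lo = np.exp(fit.coef_ - 1.96 * fit.se_)
        hi = np.exp(fit.coef_ + 1.96 * fit.se_)
        np.testing.assert_allclose(fit.or_conf_int_[:, 0], lo, rtol=1e-4)
        np.testing.assert_allclose(fit.or_conf_int_[:, 1], hi, rtol=1e-4)

    def test_constant_predictor_rejected(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        X = np.ones((6, 1))
        with pytest.raises(ModelError, match="constant"):
            fit_logistic(y, X)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ModelError, match="class"):
            fit_logistic(np.zeros(10), np.arange(10)[:, None])

    def test_separation_reported_with_diagnostics(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = np.r_[np.zeros(20), np.ones(20)]
        with pytest.raises(ModelError):
            fit_logistic(y, x[:, None])

    def test_sklearn_estimator_protocol(self):
        model = PropensityModel(predictors=["a"], tol=1e-8)
        assert model.get_params() == {"predictors": ["a"], "tol": 1e-8}
        model.set_params(predictors=None)
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"a": rng.normal(size=300)})
        y = (rng.random(300) < 1 / (1 + np.exp(-X["a"]))).astype(int)
        model.fit(X, y)
        proba = model.predict_proba(X)
        assert proba.shape == (300, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        np.testing.assert_allclose(
            model.predict_propensity(X), model.propensity_, atol=1e-10
        )


class TestCStatistic:
    def test_perfect_separation_gives_one(self):
        assert c_statistic([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores_give_half(self):
        assert c_statistic([0, 1, 0, 1], [0.3, 0.3, 0.3, 0.3]) == 0.5

    def test_equals_all_pairs_count_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(10, 51))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                y[0], y[1] = 0, 1
            p = np.round(rng.random(n), 2)  # coarse grid forces ties
            assert c_statistic(y, p) == pytest.approx(
                all_pairs_concordance(y, p), abs=1e-12
            )

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        p = rng.random(200)
        ref = c_statistic(y, p)
        for f in (lambda v: 2 * v + 1, np.exp, lambda v: v**3):
            assert c_statistic(y, f(p)) == pytest.approx(ref, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ModelError):
            c_statistic([1, 1, 1], [0.1, 0.2, 0.3])


class TestLikelihoodRatio:
    def _fits(self, seed=10, n=800, strong=True):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        eta = -2 + (1.2 * X["a"] + 0.9 * X["b"] if strong else 0 * X["a"])
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        full = PropensityModel(predictors=["a", "b", "c"]).fit(X, y)
        reduced = PropensityModel(predictors=["c"]).fit(X, y)
        return full, reduced

    def test_identical_models_give_zero_df_zero(self):
        full, _ = self._fits()
        stat, df, _ = lr_chi_square(full, full)
        assert (stat, df) == (0.0, 0)

    def test_strong_effects_give_large_significant_statistic(self):
        full, reduced = self._fits(strong=True)
        stat, df, p = lr_chi_square(full, reduced)
        assert df == 2
        assert stat > 50
        assert p < 0.001

    def test_statistic_non_negative_on_nested_pairs(self):
        for seed in range(5):
            full, reduced = self._fits(seed=seed, strong=False)
            stat, _, _ = lr_chi_square(full, reduced)
            assert stat >= 0.0

    def test_non_nested_pair_refused_with_explanation(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(300, 2)), columns=["a", "b"])
        y = (rng.random(300) < 0.3).astype(int)
        fa = PropensityModel(predictors=["a"]).fit(X, y)
        fb = PropensityModel(predictors=["b"]).fit(X, y)
        with pytest.raises(ModelError, match="not nested"):
            lr_chi_square(fa, fb)


class TestPercentImprovement:
    @pytest.mark.parametrize(
        "base,new,expected",
        [(0.627, 0.748, 19.3), (0.627, 0.725, 15.6),
         (0.648, 0.816, 25.9), (0.618, 0.735, 18.9), (0.7, 0.7, 0.0)],
    )
    def test_published_improvements(self, base, new, expected):
        assert percent_improvement(base, new) == expected

    def test_zero_base_rejected(self):
        with pytest.raises(ModelError):
            percent_improvement(0.0, 0.5)


class TestPropensityDeciles:
    def test_top_six_cases_in_top_deciles_capture_everything(self):
        p = np.linspace(0.01, 0.99, 20)
        y = np.zeros(20, int)
        y[-6:] = 1
        strat = propensity_deciles(y, p)
        assert strat.top3_capture_count == 6
        assert strat.top3_capture_percent == 100.0

    def test_counts_conserve_totals(self):
        rng = np.random.default_rng(12)
        for n in (10, 47, 1015, 2003):
            y = rng.integers(0, 2, n)
            p = rng.random(n)
            strat = propensity_deciles(y, p)
            assert strat.decile_table["n"].sum() == n
            assert strat.decile_table["pri"].sum() == y.sum()
            sizes = strat.decile_table["n"]
            assert sizes.max() - sizes.min() <= 1
            # remainder goes to the highest strata
            assert sizes.is_monotonic_increasing

    def test_staircase_on_well_specified_simulation(self):
        rng = np.random.default_rng(13)
        n = 4000
        p = rng.beta(1.2, 10, n)
        y = (rng.random(n) < p).astype(int)
        strat = propensity_deciles(y, p)
        counts = strat.decile_table["pri"].to_numpy()
        # mostly-staircase: rank correlation with decile index is strong
        from scipy.stats import spearmanr

        rho, _ = spearmanr(np.arange(10), counts)
        assert rho > 0.8

    def test_small_n_rejected(self):
        with pytest.raises(ModelError):
            propensity_deciles([0, 1, 1], [0.1, 0.5, 0.9])


class TestSplit:
    def _cohort(self, n=1015, seed=14):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"x": rng.normal(size=n), "pri": (rng.random(n) < 0.09).astype(int)}
        )

    def test_sizes_at_study_n(self):
        train, valid = split_train_validation(self._cohort(), seed=1)
        assert (len(train), len(valid)) == (660, 355)

    def test_same_seed_reproduces_identical_split(self):
        c = self._cohort()
        t1, v1 = split_train_validation(c, seed=99)
        t2, v2 = split_train_validation(c, seed=99)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(v1, v2)

    def test_partition_union_and_disjointness(self):
        c = self._cohort(n=321)
        train, valid = split_train_validation(c, seed=5)
        assert len(train) + len(valid) == 321
        assert set(train.index).isdisjoint(valid.index)
        assert set(train.index) | set(valid.index) == set(c.index)

    def test_seed_is_required(self):
        with pytest.raises(ModelError, match="seed"):
            split_train_validation(self._cohort())

    def test_warns_when_a_side_loses_a_class(self):
        c = self._cohort(n=30)
        c["pri"] = 0
        c.loc[0, "pri"] = 1
        with pytest.warns(UserWarning):
            split_train_validation(c, seed=2)


class TestModelSuite:
    def test_suite_on_simulated_cohort(self, sim_cohort_2000):
        *_, analysis = sim_cohort_2000
        suite = run_model_suite(analysis, seed=7)
        c = suite.c_statistics
        # adding informative predictors raises in-sample concordance
        assert c["model3_combined"] >= c["model1_braden"]
        tables = suite.coefficient_tables()
        assert len(tables["model1_braden"]) == 1
        assert len(tables["model2_nhsi"]) == 4
        assert len(tables["model3_combined"]) == 5
        # demographics excluded by design
        for frame in tables.values():
            assert not ({"age", "male"} & set(frame.index))
        stat, df, p = suite.lr_model3_vs_model1
        assert df == 4 and stat >= 0
        assert suite.split_sizes["training"][0] == 1300
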