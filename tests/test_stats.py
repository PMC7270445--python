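"""Model fits against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vdgrs.stats import (
    ModelFit,
    RankDeficientError,
    SampleSizeInput,
    bonferroni,
    fit_linear,
    fit_logistic,
    fit_multinomial,
    interaction_fit,
    ks_normality,
    linear_f_test,
    paired_t,
    pearson,
    sample_size,
    two_sample_t,
)


def ols_oracle(y, X):
    """Brute-force normal equations with unbiased residual variance."""
    X = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
    y = np.asarray(y, dtype=float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
    t = beta / se
    p = 2 * sps.t.sf(np.abs(t), df)
    return beta, se, p


class TestLinear:
    def test_exact_fit(self):
        x = np.arange(5.0)
        fit = fit_linear(2 * x + 1, x, names=["x"])
        assert fit["x"]["beta"] == pytest.approx(2.0)
        assert fit["intercept"]["beta"] == pytest.approx(1.0)
        assert fit["x"]["se"] == pytest.approx(0.0, abs=1e-12)

    def test_six_point_fixture_matches_normal_equations(self):
        x = np.arange(1.0, 7.0)
        y = np.array([2.0, 4.0, 5.0, 4.0, 5.0, 7.0])
        fit = fit_linear(y, x, names=["x"])
        beta, se, p = ols_oracle(y, x[:, None])
        assert fit.beta == pytest.approx(beta, rel=1e-10)
        assert fit.se == pytest.approx(se, rel=1e-10)
        assert fit.p == pytest.approx(p, rel=1e-10)
        # hand-computed: slope 13.5/17.5, intercept 1.8
        assert fit["x"]["beta"] == pytest.approx(13.5 / 17.5)
        assert fit["intercept"]["beta"] == pytest.approx(1.8)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(size=30)
        fit1 = fit_linear(y, X)
        perm = rng.permutation(30)
        fit2 = fit_linear(y[perm], X[perm])
        assert fit1.beta == pytest.approx(fit2.beta, rel=1e-10)

    def test_random_designs_match_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = rng.integers(10, 50)
            k = rng.integers(1, 5)
            X = rng.normal(size=(n, k))
            y = rng.normal(size=n)
            fit = fit_linear(y, X)
            beta, se, p = ols_oracle(y, X)
            np.testing.assert_allclose(fit.beta, beta, rtol=1e-8)
            np.testing.assert_allclose(fit.se, se, rtol=1e-8)

    def test_rank_deficiency_names_columns(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(RankDeficientError) as err:
            fit_linear(np.arange(10.0), X)
        assert set(err.value.columns) & {"a", "b"}

    def test_incomplete_rows_dropped(self):
        x = np.arange(10.0)
        y = 3 * x
        y[4] = np.nan
        fit = fit_linear(y, x)
        assert fit.n_used == 9

    def test_partial_f_test_on_null_column(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=200)
        noise = rng.normal(size=200)
        y = 2 * x + rng.normal(size=200)
        full = pd.DataFrame({"x": x, "noise": noise})
        f, p, n = linear_f_test(y, full, full[["x"]])
        assert n == 200
        assert p > 0.001  # the extra column explains nothing systematic


class TestLogistic:
    def test_two_by_two_table_log_odds(self):
        # exposed: 10 events / 10 non-events; unexposed: 5 / 20 -> OR = 4
        y = np.r_[np.ones(10), np.zeros(10), np.ones(5), np.zeros(20)]
        x = np.r_[np.ones(20), np.zeros(25)]
        fit = fit_logistic(y, x, names=["exposed"])
        assert fit["exposed"]["beta"] == pytest.approx(np.log(4.0), abs=1e-6)
        se_closed = np.sqrt(1 / 10 + 1 / 10 + 1 / 5 + 1 / 20)
        assert fit["exposed"]["se"] == pytest.approx(se_closed, abs=1e-6)

    def test_intercept_only_is_logit_of_proportion(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logistic(y, np.zeros((100, 0)), names=[])
        assert fit["intercept"]["beta"] == pytest.approx(np.log(30 / 70), abs=1e-8)

    def test_null_covariate_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=400)
        y = rng.random(400) < 0.5
        fit = fit_logistic(y.astype(float), x, names=["x"])
        term = fit["x"]
        assert abs(term["beta"]) < 3 * term["se"]

    def test_complete_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        fit = fit_logistic(x.copy(), x, names=["x"])
        assert not fit.converged

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(20), np.arange(20.0))


class TestMultinomial:
    def test_two_levels_collapse_to_logistic(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = np.where(rng.random(200) < 1 / (1 + np.exp(-x)), "case", "ref")
        fits = fit_multinomial(y, x, reference="ref", names=["x"])
        direct = fit_logistic((y == "case").astype(float), x, names=["x"])
        assert fits["case"].beta == pytest.approx(direct.beta, rel=1e-8)

    def test_reference_swap_flips_sign(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=300)
        y = np.where(rng.random(300) < 1 / (1 + np.exp(-0.8 * x)), "a", "b")
        fit_ab = fit_multinomial(y, x, reference="b", names=["x"])["a"]
        fit_ba = fit_multinomial(y, x, reference="a", names=["x"])["b"]
        assert fit_ab["x"]["beta"] == pytest.approx(-fit_ba["x"]["beta"], rel=1e-6)

    def test_three_category_recovery(self):
        # one-vs-reference generating process, n=5000, known log-odds
        rng = np.random.default_rng(21)
        n = 5000
        x = rng.normal(size=n)
        true = {"b": (-1.0, 0.7), "c": (-1.5, -0.5)}
        y = np.full(n, "a", dtype=object)
        for level, (b0, b1) in true.items():
            pick = rng.random(n) < 1 / (1 + np.exp(-(b0 + b1 * x)))
            y[(y == "a") & pick] = level
        fits = fit_multinomial(y, x, reference="a", names=["x"])
        for level, (_, b1) in true.items():
            term = fits[level]["x"]
            assert abs(term["beta"] - b1) < 3 * term["se"]


class TestInteraction:
    def test_product_term_recovery(self):
        rng = np.random.default_rng(7)
        n = 2000
        g = rng.binomial(12, 0.28, size=n).astype(float)
        e = rng.normal(20, 10, size=n)
        gamma = 0.08
        y = 33.9 + gamma * (g - g.mean()) * (e - e.mean()) + rng.normal(0, 2.5, n)
        fit = interaction_fit(y, g, e)
        term = fit["grs:vitd"]
        assert abs(term["beta"] - gamma) < 3 * term["se"]

    def test_constant_exposure_rank_deficient(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(12, 0.3, 50).astype(float)
        with pytest.raises(RankDeficientError):
            interaction_fit(rng.normal(size=50), g, np.full(50, 20.0))

    def test_covariates_enter_adjustment_set(self):
        rng = np.random.default_rng(4)
        n = 100
        cov = pd.DataFrame({"age": rng.normal(30, 5, n)})
        fit = interaction_fit(
            rng.normal(size=n), rng.binomial(12, 0.3, n), rng.normal(20, 8, n),
            covariates=cov,
        )
        assert fit.adjustment_set == ["age"]
        assert "age" in fit.terms


class TestClassicalTests:
    def test_identical_groups_t_zero(self):
        group = [1.0, 2.0, 3.0, 4.0]
        t, p = two_sample_t(group, group)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_two_sample_null_rejection_rate(self):
        rng = np.random.default_rng(123)
        rejections = 0
        reps = 500
        for _ in range(reps):
            _, p = two_sample_t(rng.normal(size=20), rng.normal(size=20))
            rejections += p < 0.05
        rate = rejections / reps
        mc_se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 2 * mc_se + 1e-12

    def test_paired_identical_is_zero(self):
        x = [3.0, 4.0, 5.0]
        assert paired_t(x, x) == (0.0, 1.0)

    def test_pearson_perfect_line(self):
        x = np.arange(10.0)
        r, _ = pearson(x, x)
        assert r == pytest.approx(1.0)

    def test_pearson_matches_covariance_ratio(self):
        x = np.array([1.2, 3.4, 2.2, 5.1, 4.4, 6.0, 7.3, 0.8, 5.9, 3.1])
        y = np.array([2.0, 3.9, 2.5, 4.8, 5.2, 5.5, 8.1, 1.2, 6.3, 2.7])
        r, _ = pearson(x, y)
        hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(hand, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            two_sample_t([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_ks_detects_gross_non_normality(self):
        rng = np.random.default_rng(6)
        normal = rng.normal(size=500)
        skewed = rng.exponential(size=500)
        _, p_normal = ks_normality(normal)
        _, p_skewed = ks_normality(skewed)
        assert p_normal > 0.05
        assert p_skewed < 0.01


class TestMultiplicityAndPower:
    @pytest.mark.parametrize(
        "m,threshold,display",
        [(9, 0.05 / 9, 0.006), (18, 0.05 / 18, 0.003), (1, 0.05, 0.05)],
    )
    def test_bonferroni_families(self, m, threshold, display):
        family = bonferroni(0.05, m)
        assert family.threshold == pytest.approx(threshold)
        assert family.threshold_display == pytest.approx(display)
        assert family.threshold <= family.alpha_family

    def test_bonferroni_scales_as_one_over_m(self):
        base = bonferroni(0.05, 1).threshold
        for m in (2, 5, 9, 18, 100):
            assert bonferroni(0.05, m).threshold == pytest.approx(base / m)

    def test_bonferroni_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)

    def test_worked_power_example(self):
        n, ceiling = sample_size(SampleSizeInput(1.96, 1.28, 18.5, 13.08))
        assert n == pytest.approx(41.96, abs=0.05)
        assert ceiling == 42

    def test_hand_arithmetic(self):
        n, _ = sample_size(SampleSizeInput(1.0, 1.0, 1.0, 2.0))
        assert n == pytest.approx(2.0)

    def test_doubling_sd_quadruples_n(self):
        n1, _ = sample_size(SampleSizeInput(1.96, 1.28, 10.0, 5.0))
        n2, _ = sample_size(SampleSizeInput(1.96, 1.28, 20.0, 5.0))
        assert n2 == pytest.approx(4 * n1)

    def test_sign_flip_invariance(self):
        n_pos, _ = sample_size(SampleSizeInput(1.96, 1.28, 18.5, 13.08))
        n_neg, _ = sample_size(SampleSizeInput(1.96, 1.28, 18.5, -13.08))
        assert n_pos == n_neg

    def test_zero_difference_rejected(self):
        with pytest.raises(ValueError):
            SampleSizeInput(1.96, 1.28, 18.5, 0.0)
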