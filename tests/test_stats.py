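"""Correlation, ANOVA, and block-sequential regression against independent
oracles (direct summation, hand sums of squares, normal equations, and the
scipy/statsmodels reference implementations)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from whmt import (
    DegenerateInputError,
    RegressionSpec,
    one_way_anova,
    pearson_r,
    sequential_ols,
)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=5000), rng.normal(size=5000)
        r, _ = pearson_r(x, y)
        assert abs(r) < 0.05

    def test_matches_summation_oracle(self):
        rng = np.random.default_rng(14)
        x, y = rng.normal(size=10), rng.normal(size=10)
        # direct covariance / (sigma_x sigma_y) by explicit loops
        mx, my = sum(x) / 10, sum(y) / 10
        cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
        sx = sum((a - mx) ** 2 for a in x) ** 0.5
        sy = sum((b - my) ** 2 for b in y) ** 0.5
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(cov / (sx * sy), rel=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(15)
        x, y = rng.normal(size=40), rng.normal(size=40)
        r, p = pearson_r(x, y)
        ref = sps.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_listwise_deletion(self):
        x = np.array([1.0, 2, 3, np.nan, 5, 6])
        y = np.array([2.0, 4, 6, 8, np.nan, 12])
        r, _ = pearson_r(x, y)
        assert r == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])


class TestAnova:
    def test_toy_fixture_matches_hand_sums_of_squares(self):
        g1, g2 = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = one_way_anova([g1, g2])
        grand = np.mean(g1 + g2)
        ssb = 3 * (np.mean(g1) - grand) ** 2 + 3 * (np.mean(g2) - grand) ** 2
        ssw = sum((v - np.mean(g1)) ** 2 for v in g1) + sum(
            (v - np.mean(g2)) ** 2 for v in g2
        )
        assert res.F == pytest.approx((ssb / 1) / (ssw / 4), rel=1e-12)
        assert (res.df1, res.df2) == (1, 4)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(16)
        groups = [rng.normal(loc, 1.0, size=n) for loc, n in [(0, 20), (0.5, 25), (1, 15)]]
        res = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_equal_means_large_n_not_significant(self):
        rng = np.random.default_rng(17)
        groups = [rng.normal(0, 1, 500) for _ in range(4)]
        res = one_way_anova(groups)
        assert res.p > 0.05

    def test_all_identical_data_is_zero(self):
        res = one_way_anova([[3.0, 3.0, 3.0], [3.0, 3.0, 3.0]])
        assert res.F == 0.0

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(18)
        a, b = rng.normal(0, 1, 30), rng.normal(0.4, 1, 35)
        res = one_way_anova([a, b])
        t = sps.ttest_ind(a, b)  # pooled-variance two-sample t
        assert res.F == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p == pytest.approx(t.pvalue, rel=1e-8)


def toy_frame(n=200, seed=19, beta=(0.0, 0.5, 0.3), interaction=0.0):
    rng = np.random.default_rng(seed)
    age = rng.uniform(24, 80, n)
    parental = rng.integers(0, 2, n).astype(float)
    romantic = rng.integers(0, 2, n).astype(float)
    y = (
        beta[0] * age
        + beta[1] * parental
        + beta[2] * romantic
        + interaction * (parental - parental.mean()) * (romantic - romantic.mean())
        + rng.normal(0, 1.0, n)
    )
    return pd.DataFrame(
        {"y": y, "age": age, "parental": parental, "romantic": romantic}
    )


SPEC = RegressionSpec(outcome="y", block1=["age", "parental", "romantic"])


class TestSequentialOLS:
    def test_exact_linear_outcome_r2_one_no_change(self):
        data = toy_frame(seed=20)
        data["y"] = 1.0 + 2.0 * data["age"] - 3.0 * data["parental"]
        fit = sequential_ols(SPEC, data)
        assert fit.r2_block1 == pytest.approx(1.0)
        assert fit.r2_change == pytest.approx(0.0, abs=1e-9)

    def test_coefficients_match_normal_equations_oracle(self):
        # 8-row fixture solved independently via X'X beta = X'y.
        rng = np.random.default_rng(21)
        data = pd.DataFrame(
            {
                "y": rng.normal(size=8),
                "age": rng.uniform(24, 80, 8),
                "parental": [0, 1, 0, 1, 1, 0, 1, 0],
                "romantic": [1, 1, 0, 0, 1, 0, 0, 1],
            }
        )
        fit = sequential_ols(
            RegressionSpec(outcome="y", block1=["age", "parental", "romantic"], interactions=False),
            data,
        )
        X = np.column_stack(
            [np.ones(8), data["age"], data["parental"], data["romantic"]]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ data["y"].to_numpy())
        sy = data["y"].std(ddof=1)
        for i, name in enumerate(["age", "parental", "romantic"], start=1):
            expect = beta[i] * data[name].std(ddof=1) / sy
            assert fit.beta_block1[name] == pytest.approx(expect, rel=1e-9)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        data = toy_frame(seed=22, interaction=0.8)
        fit = sequential_ols(SPEC, data)
        X1 = sm.add_constant(data[["age", "parental", "romantic"]])
        ref1 = sm.OLS(data["y"], X1).fit()
        assert fit.r2_block1 == pytest.approx(ref1.rsquared, rel=1e-10)
        centered = data[["age", "parental", "romantic"]] - data[
            ["age", "parental", "romantic"]
        ].mean()
        X2 = X1.copy()
        X2["age x parental"] = centered["age"] * centered["parental"]
        X2["age x romantic"] = centered["age"] * centered["romantic"]
        X2["parental x romantic"] = centered["parental"] * centered["romantic"]
        ref2 = sm.OLS(data["y"], X2).fit()
        assert fit.r2 == pytest.approx(ref2.rsquared, rel=1e-10)
        assert fit.adj_r2 == pytest.approx(ref2.rsquared_adj, rel=1e-10)
        assert fit.F == pytest.approx(ref2.fvalue, rel=1e-8)
        assert (fit.df1, fit.df2) == (int(ref2.df_model), int(ref2.df_resid))

    def test_r2_monotone_across_blocks(self):
        for seed in range(23, 28):
            fit = sequential_ols(SPEC, toy_frame(seed=seed))
            assert fit.r2 >= fit.r2_block1 - 1e-12
            assert fit.r2_change >= -1e-12
            assert fit.adj_r2 <= fit.r2 + 1e-12

    def test_single_predictor_beta_equals_pearson_r(self):
        data = toy_frame(seed=28)
        fit = sequential_ols(
            RegressionSpec(outcome="y", block1=["age"], interactions=False), data
        )
        r, _ = pearson_r(data["age"], data["y"])
        assert fit.beta_block1["age"] == pytest.approx(r, rel=1e-10)

    def test_interaction_columns_are_centered(self):
        data = toy_frame(seed=29)
        centered = data[["age", "parental"]] - data[["age", "parental"]].mean()
        prod = centered["age"] * centered["parental"]
        # mean of a product of centered columns equals their covariance, small
        # relative to the column scale, and the fit must reproduce this design
        fit = sequential_ols(SPEC, data)
        assert set(fit.beta_block2) == {
            "age x parental", "age x romantic", "parental x romantic",
        }
        assert abs(prod.mean()) < np.abs(prod).max()

    def test_constant_predictor_dropped_and_recorded(self):
        data = toy_frame(seed=30)
        data["parental"] = 1.0  # everyone a parent, as in a child-raters subsample
        fit = sequential_ols(SPEC, data)
        assert "parental" in fit.dropped
        assert "parental" not in fit.beta_block1
        assert all("parental" not in name for name in fit.beta_block2)

    def test_collinear_predictor_dropped(self):
        data = toy_frame(seed=31)
        data["parental"] = data["romantic"]  # exact collinearity
        fit = sequential_ols(SPEC, data)
        assert "romantic" in fit.dropped or "parental" in fit.dropped

    def test_parameter_recovery_pure_romantic_effect(self):
        data = toy_frame(n=2000, seed=32, beta=(0.0, 0.0, 2.0))
        fit = sequential_ols(SPEC, data)
        assert fit.beta_block1["romantic"] > 0.5
        assert abs(fit.beta_block1["age"]) < 0.1
        assert abs(fit.beta_block1["parental"]) < 0.1

    def test_too_few_rows_degenerate(self):
        with pytest.raises(DegenerateInputError):
            sequential_ols(SPEC, toy_frame(n=4, seed=33))
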