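"""Prevalence intervals, chi-square + adjusted residuals, logistic regression."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bcrisknet.stats import (
    ContingencyTable,
    DegenerateTableError,
    SeparationError,
    adjusted_residuals,
    chi_square,
    fit_logistic,
    prevalence_ci,
    univariate_screen,
)


class TestPrevalenceCI:
    @pytest.mark.parametrize(
        "x, n, expected",
        [
            (100, 5601, (1.8, 1.5, 2.2)),
            (7, 166, (4.2, 2.1, 8.4)),
            (8, 889, (0.9, 0.5, 1.8)),
            (9, 193, (4.7, 2.5, 8.6)),
            (38, 1299, (2.9, 2.1, 4.0)),
        ],
    )
    def test_wilson_reproduces_reported_percentages(self, x, n, expected):
        assert prevalence_ci(x, n).as_percent() == expected

    def test_zero_cases_boundary(self):
        est = prevalence_ci(0, 50)
        assert est.rate == 0.0
        assert est.lower == 0.0
        assert est.upper > 0.0

    def test_n_zero_undefined(self):
        with pytest.raises(ValueError, match="n = 0"):
            prevalence_ci(0, 0)

    def test_wilson_against_score_equation_root(self):
        """Independent oracle: Wilson bounds are the roots of
        (p_hat - p)^2 = z^2 p(1-p)/n."""
        from scipy.optimize import brentq

        x, n = 100, 5601
        phat = x / n
        z = sps.norm.ppf(0.975)

        def score(p):
            return (phat - p) ** 2 - z**2 * p * (1 - p) / n

        lo = brentq(score, 1e-9, phat)
        hi = brentq(score, phat, 1 - 1e-9)
        est = prevalence_ci(x, n)
        assert est.lower == pytest.approx(lo, abs=1e-10)
        assert est.upper == pytest.approx(hi, abs=1e-10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=1, max_value=10_000),
        frac=st.floats(min_value=0.0, max_value=1.0),
        method=st.sampled_from(["wilson", "clopper_pearson", "wald"]),
    )
    def test_bounds_bracket_rate_in_unit_interval(self, n, frac, method):
        x = int(round(frac * n))
        est = prevalence_ci(x, n, method=method)
        assert 0.0 <= est.lower <= est.rate <= est.upper <= 1.0


class TestChiSquare:
    def test_uniform_table_is_null(self):
        stat, dof, p = chi_square([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert dof == 1
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # E = 20 in all four cells, X^2 = 4 * 100/20
        stat, dof, p = chi_square([[30, 10], [10, 30]])
        assert stat == pytest.approx(20.0)
        assert dof == 1

    def test_zero_margin_degenerate(self):
        with pytest.raises(DegenerateTableError):
            chi_square([[0, 0], [5, 7]])

    def test_monotone_p_in_statistic(self):
        # p decreases as association strengthens at fixed df
        stats_ = [chi_square([[20 + d, 20 - d], [20 - d, 20 + d]]) for d in (2, 6, 12)]
        xs = [s[0] for s in stats_]
        ps = [s[2] for s in stats_]
        assert xs == sorted(xs)
        assert ps == sorted(ps, reverse=True)

    def test_statistic_equals_sum_of_squared_pearson_residuals(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            shape = rng.integers(2, 5, size=2)
            obs = rng.integers(1, 40, size=shape)
            stat, _, _ = chi_square(obs)
            n = obs.sum()
            e = obs.sum(1, keepdims=True) @ obs.sum(0, keepdims=True) / n
            pearson = (obs - e) / np.sqrt(e)
            assert stat == pytest.approx((pearson**2).sum(), rel=1e-12)


class TestAdjustedResiduals:
    def test_null_table_all_zero(self):
        r = adjusted_residuals([[10, 10], [10, 10]])
        assert np.allclose(r, 0.0)

    def test_hand_computed_example(self):
        r = adjusted_residuals([[30, 10], [10, 30]])
        assert r[0, 0] == pytest.approx(4.472135955, abs=1e-9)
        assert np.allclose(np.abs(r), 4.472135955)

    def test_two_by_two_residual_squared_equals_chi_square(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            obs = rng.integers(1, 60, size=(2, 2))
            stat, _, _ = chi_square(obs)
            r = adjusted_residuals(obs)
            assert np.allclose(r**2, stat, rtol=1e-10)

    def test_row_and_column_deviation_sums_vanish(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            obs = rng.integers(1, 30, size=(3, 4))
            n = obs.sum()
            e = obs.sum(1, keepdims=True) @ obs.sum(0, keepdims=True) / n
            dev = obs - e
            assert np.allclose(dev.sum(axis=0), 0.0, atol=1e-9)
            assert np.allclose(dev.sum(axis=1), 0.0, atol=1e-9)

    def test_flagging_threshold(self):
        ct = ContingencyTable(np.array([[30, 10], [10, 30]]))
        flags = ct.flagged()
        assert flags[0, 0] == 1 and flags[0, 1] == -1


class TestFitLogistic:
    def test_single_binary_covariate_matches_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 600)
        p = np.where(x == 1, 0.25, 0.1)
        y = (rng.random(600) < p).astype(float)
        a = ((x == 1) & (y == 1)).sum()
        b = ((x == 1) & (y == 0)).sum()
        c = ((x == 0) & (y == 1)).sum()
        d = ((x == 0) & (y == 0)).sum()
        fit = fit_logistic(x.astype(float), y)
        assert fit.converged
        assert fit.coef[1] == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)

    def test_agrees_with_statsmodels(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(500, 3))
        eta = -2.0 + X @ np.array([0.8, -0.5, 0.2])
        y = (rng.random(500) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(fit.coef, ref.params, atol=1e-6)
        assert np.allclose(fit.se, ref.bse, atol=1e-5)

    def test_constant_outcome_raises(self):
        with pytest.raises(SeparationError):
            fit_logistic(np.ones((10, 1)), np.zeros(10))

    def test_perfect_predictor_flagged(self):
        y = np.array([0.0] * 20 + [1.0] * 20)
        x = y.copy()
        with pytest.warns(RuntimeWarning, match="separation"):
            fit = fit_logistic(x, y)
        assert fit.separation

    def test_wald_ci_contains_or(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=400)
        y = (rng.random(400) < 1 / (1 + np.exp(-(-1 + x)))).astype(float)
        fit = fit_logistic(x, y)
        ci = fit.or_ci
        assert np.all(ci[:, 0] <= fit.odds_ratios)
        assert np.all(fit.odds_ratios <= ci[:, 1])


class TestUnivariateScreen:
    def test_planted_effect_detected(self):
        # OR = 2, 30% exposure, 5% baseline, n = 5000 -> essentially certain
        rng = np.random.default_rng(6)
        n = 5000
        exposed = rng.random(n) < 0.3
        logit = np.log(0.05 / 0.95) + np.log(2.0) * exposed
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        age = rng.integers(40, 80, n).astype(float)
        res = univariate_screen(
            pd.DataFrame({"exp": np.where(exposed, "yes", "no")}),
            pd.Series(y), pd.Series(age),
        )
        assert bool(res.loc[res["variable"] == "exp", "selected"].iloc[0])

    def test_variable_identical_to_outcome_excluded(self):
        rng = np.random.default_rng(7)
        y = (rng.random(400) < 0.3).astype(int)
        age = rng.integers(40, 80, 400).astype(float)
        res = univariate_screen(
            pd.DataFrame({"leak": np.where(y == 1, "a", "b")}),
            pd.Series(y), pd.Series(age),
        )
        row = res.iloc[0]
        assert row["status"] == "separation"
        assert not row["selected"]

    def test_constant_variable_skipped(self):
        rng = np.random.default_rng(8)
        y = (rng.random(200) < 0.2).astype(int)
        age = rng.integers(40, 80, 200).astype(float)
        res = univariate_screen(
            pd.DataFrame({"const": ["x"] * 200}), pd.Series(y), pd.Series(age)
        )
        assert res.iloc[0]["status"] == "constant"
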