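"""Exact rate test against an enumeration oracle; WLS and Breusch-Pagan."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from clonoscope import breusch_pagan, exact_rate_test, wls_fit


def _oracle_pvalues(y1, n1, y0, n0):
    """Exact-rational enumeration of the conditional binomial distribution."""
    T = y1 + y0
    p = Fraction(n1, n1 + n0)
    pmf = [comb(T, k) * p**k * (1 - p) ** (T - k) for k in range(T + 1)]
    one = sum(pmf[y1:])
    two = sum(q for q in pmf if q <= pmf[y1])
    return float(one), float(two)


class TestExactRateTest:
    def test_primary_contrast_tail_value(self):
        # 65 mutations in 12 animals vs 0 in 6: upper tail is (2/3)^65
        r = exact_rate_test(65, 12, 0, 6)
        assert r.p_one_sided == pytest.approx((2 / 3) ** 65, rel=1e-12)
        assert r.p_two_sided < 0.01
        assert r.rate_ratio_mle == float("inf")

    def test_small_count_contrast_matches_enumeration(self):
        r = exact_rate_test(5, 12, 0, 6)
        one, two = _oracle_pvalues(5, 12, 0, 6)
        assert r.p_one_sided == pytest.approx(one, rel=1e-12)
        assert r.p_two_sided == pytest.approx(two, rel=1e-12)

    def test_symmetric_mode_two_sided_p_is_one(self):
        r = exact_rate_test(4, 10, 4, 10)
        assert r.p_two_sided == pytest.approx(1.0)
        assert r.rate_ratio_mle == pytest.approx(1.0)

    def test_zero_total_degenerate(self):
        r = exact_rate_test(0, 12, 0, 6)
        assert r.p_one_sided == 1.0 and r.p_two_sided == 1.0
        assert np.isnan(r.rate_ratio_mle)

    def test_one_sided_below_two_sided_in_upper_tail(self):
        r = exact_rate_test(10, 5, 2, 5)
        assert r.p_one_sided <= r.p_two_sided <= 1.0

    @pytest.mark.parametrize("n1,n0", [(12, 6), (5, 5), (1, 9)])
    def test_matches_enumeration_oracle_over_totals(self, n1, n0):
        """Agreement with exact-rational enumeration for all totals <= 200."""
        rng = np.random.default_rng(n1 * 100 + n0)
        for T in range(0, 201):
            # all splits for small totals, random splits for larger ones
            ys = range(T + 1) if T <= 30 else rng.integers(0, T + 1, size=8)
            for y1 in ys:
                y1 = int(y1)
                r = exact_rate_test(y1, n1, T - y1, n0)
                one, two = _oracle_pvalues(y1, n1, T - y1, n0)
                assert r.p_one_sided == pytest.approx(one, rel=1e-9, abs=1e-300)
                assert r.p_two_sided == pytest.approx(two, rel=1e-7, abs=1e-300)

    def test_type_i_error_conservative_under_null(self):
        """Simulated size at nominal 0.05 stays <= 0.055 (exact tests are conservative)."""
        rng = np.random.default_rng(3)
        n1, n0, lam, reps = 12, 6, 2.0, 10_000
        y1 = rng.poisson(lam * n1, reps)
        y0 = rng.poisson(lam * n0, reps)
        rejected = sum(
            exact_rate_test(int(a), n1, int(b), n0).p_two_sided <= 0.05
            for a, b in zip(y1, y0)
        )
        assert rejected / reps <= 0.055

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            exact_rate_test(-1, 12, 0, 6)
        with pytest.raises(ValueError):
            exact_rate_test(1, 0, 0, 6)


def _wls_closed_form(y, X, w):
    """Weighted normal equations: (X'WX)^-1 X'Wy."""
    Xm = np.column_stack([np.ones(len(y)), X])
    W = np.diag(w)
    return np.linalg.solve(Xm.T @ W @ Xm, Xm.T @ W @ y)


class TestWls:
    def test_matches_weighted_normal_equations(self, rng):
        for _ in range(20):
            n = 50
            X = rng.normal(size=(n, 3))
            y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(size=n)
            w = rng.uniform(0.2, 5.0, size=n)
            fit = wls_fit(y, pd.DataFrame(X, columns=list("abc")), weights=w)
            expected = _wls_closed_form(y, X, w)
            np.testing.assert_allclose(fit.params.to_numpy(), expected, rtol=1e-8)

    def test_equal_weights_reduce_to_ols(self, rng):
        n = 40
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = 2 + 3 * X["x"] + rng.normal(size=n)
        wls = wls_fit(y, X, weights=np.full(n, 7.0))
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(wls.params.to_numpy(), ols.params.to_numpy())
        np.testing.assert_allclose(wls.pvalues.to_numpy(), ols.pvalues.to_numpy())

    def test_exact_linear_outcome_zero_residuals(self, rng):
        n = 30
        X = pd.DataFrame({"x": rng.normal(size=n), "z": rng.normal(size=n)})
        y = 1 + 2 * X["x"] - 3 * X["z"]
        fit = wls_fit(y, X)
        np.testing.assert_allclose(fit.resid, 0, atol=1e-10)
        assert (fit.pvalues[["x", "z"]] < 1e-10).all()

    def test_residuals_orthogonal_to_weighted_design(self, rng):
        n = 60
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = 1 + X["x"] + rng.normal(size=n)
        w = rng.uniform(0.5, 2.0, size=n)
        fit = wls_fit(y, X, weights=w)
        Xm = np.column_stack([np.ones(n), X["x"]])
        score = Xm.T @ (w * fit.resid)
        np.testing.assert_allclose(score, 0, atol=1e-8 * np.abs(y).sum())

    def test_singular_design_names_columns(self, rng):
        n = 20
        x = rng.normal(size=n)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(np.linalg.LinAlgError, match="x2"):
            wls_fit(rng.normal(size=n), X)

    def test_missing_outcomes_dropped(self, rng):
        n = 20
        X = pd.DataFrame({"x": rng.normal(size=n)})
        y = 1 + X["x"] + rng.normal(size=n)
        y[3] = np.nan
        fit = wls_fit(y, X)
        assert fit.nobs == n - 1

    def test_group_effect_recovered_with_feasible_weights(self, rng):
        """True +5 group shift on myeloid % is recovered within 2 SE.

        A +/- 2 SE interval covers ~95.4% asymptotically; finite-sample df
        and estimated weights shave a little, and 500 replicates carry ~1%
        Monte Carlo error, so the bound allows that slack.
        """
        cover = 0
        reps = 500
        for _ in range(reps):
            n = 47
            g = (np.arange(n) < 36).astype(float)
            age = rng.uniform(14, 20, n)
            sexf = (rng.random(n) < 0.5).astype(float)
            y = 25 + 5 * g + 0.3 * age - sexf + rng.normal(0, 1 + 2 * g)
            X = pd.DataFrame({"group": g, "age": age, "sexf": sexf})
            fit = wls_fit(y, X, group=g)
            cover += abs(fit.params["group"] - 5) <= 2 * fit.bse["group"]
        assert cover / reps >= 0.93


def _bp_oracle(resid, X):
    """Auxiliary regression by hand: n * R-squared of e^2 on the design."""
    Xm = np.column_stack([np.ones(len(resid)), X])
    e2 = resid**2
    beta = np.linalg.lstsq(Xm, e2, rcond=None)[0]
    fitted = Xm @ beta
    ss_res = np.sum((e2 - fitted) ** 2)
    ss_tot = np.sum((e2 - e2.mean()) ** 2)
    return len(resid) * (1 - ss_res / ss_tot)


class TestBreuschPagan:
    def test_matches_auxiliary_regression_oracle(self, rng):
        n = 80
        x = rng.normal(size=n)
        y = 1 + x + rng.normal(size=n) * (1 + 0.5 * np.abs(x))
        X = pd.DataFrame({"x": x})
        resid = sm.OLS(y, sm.add_constant(X)).fit().resid
        stat, p = breusch_pagan(resid, X)
        assert stat == pytest.approx(_bp_oracle(np.asarray(resid), x[:, None]), rel=1e-8)

    def test_constant_residuals_give_zero_stat(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        stat, p = breusch_pagan(np.zeros(10), X)
        assert (stat, p) == (0.0, 1.0)

    def test_null_rejection_rate_close_to_nominal(self, rng):
        """Homoskedastic type-I error ~ 0.05 over 2,000 replicates."""
        reps, n, rejected = 2000, 100, 0
        for _ in range(reps):
            x = rng.normal(size=n)
            y = 1 + 0.5 * x + rng.normal(size=n)
            X = pd.DataFrame({"x": x})
            resid = sm.OLS(y, sm.add_constant(X)).fit().resid
            _stat, p = breusch_pagan(resid, X)
            rejected += p <= 0.05
        assert 0.03 <= rejected / reps <= 0.07

    def test_power_against_variance_trend(self, rng):
        """Variance proportional to a design column is detected more than half the time."""
        reps, n, rejected = 200, 200, 0
        for _ in range(reps):
            x = rng.uniform(1, 4, size=n)
            y = 1 + x + rng.normal(size=n) * x
            X = pd.DataFrame({"x": x})
            resid = sm.OLS(y, sm.add_constant(X)).fit().resid
            _stat, p = breusch_pagan(resid, X)
            rejected += p <= 0.05
        assert rejected / reps > 0.5
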