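"""Tests for prior-effect rescaling, calibration, and the co-data filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from priorstack.calibration import (
    DEFAULT_TAU_GRID,
    build_cumulative_design,
    exponential_calibrate,
    filter_codata,
    isotonic_calibrate,
    recover_gamma,
    rescale_priors,
)
from priorstack.data import GlmDataset


class TestRescale:
    def test_divides_by_max_abs(self):
        ps = rescale_priors(np.array([[2.0], [-4.0], [0.0]]))
        np.testing.assert_allclose(ps.effects[:, 0], [0.5, -1.0, 0.0])
        assert not ps.degenerate[0]

    def test_zero_column_flagged_degenerate(self):
        ps = rescale_priors(np.zeros((3, 1)))
        np.testing.assert_allclose(ps.effects, 0.0)
        assert ps.degenerate[0]

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            rescale_priors(np.array([[1.0], [np.inf]]))

    @given(c=st.floats(min_value=0.1, max_value=50.0))
    @settings(deadline=None, max_examples=20)
    def test_rescaling_is_positive_scale_invariant(self, c):
        rng = np.random.default_rng(5)
        z = rng.uniform(-2, 2, 12)
        a = rescale_priors(z).effects
        b = rescale_priors(c * z).effects
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestCumulativeDesign:
    def test_worked_example_with_negative_block(self, rng):
        X = rng.standard_normal((9, 4))
        z = np.array([-0.5, -0.2, 0.3, 0.9])
        d = build_cumulative_design(X, z)
        assert d.q == 2
        np.testing.assert_allclose(d.W[:, 0], X[:, 0])
        np.testing.assert_allclose(d.W[:, 1], X[:, 0] + X[:, 1])
        np.testing.assert_allclose(d.W[:, 2], X[:, 2] + X[:, 3])
        np.testing.assert_allclose(d.W[:, 3], X[:, 3])
        np.testing.assert_array_equal(d.signs, [-1, -1, 1, 1])

    def test_all_positive_priors(self, rng):
        X = rng.standard_normal((6, 3))
        z = np.array([0.2, 0.5, 0.9])
        d = build_cumulative_design(X, z)
        assert d.q == 0
        np.testing.assert_allclose(d.W[:, 0], X.sum(axis=1))
        np.testing.assert_allclose(d.W[:, -1], X[:, 2])

    def test_zero_priors_excluded(self, rng):
        X = rng.standard_normal((6, 4))
        z = np.array([0.0, 0.5, 0.0, -0.3])
        d = build_cumulative_design(X, z)
        assert d.n_groups == 2 and d.q == 1
        gamma = recover_gamma(np.array([-0.4, 0.7]), d)
        assert gamma[0] == 0.0 and gamma[2] == 0.0

    def test_linear_predictor_identity(self, rng):
        """delta' W row equals (recovered gamma)' X row to 1e-12."""
        n, p = 10, 6
        X = rng.standard_normal((n, p))
        z = rng.uniform(-1, 1, p)
        d = build_cumulative_design(X, z)
        for _ in range(5):
            delta = np.where(
                d.signs < 0, -rng.random(d.n_groups), rng.random(d.n_groups)
            )
            gamma = recover_gamma(delta, d)
            np.testing.assert_allclose(d.W @ delta, X @ gamma, atol=1e-12)

    def test_recover_gamma_worked_example(self, rng):
        X = rng.standard_normal((5, 4))
        z = np.array([-0.6, -0.1, 0.4, 0.8])
        d = build_cumulative_design(X, z)
        gamma = recover_gamma(np.array([-1.0, -0.5, 0.3, 0.2]), d)
        np.testing.assert_allclose(gamma, [-1.5, -0.5, 0.3, 0.5])

    def test_recover_gamma_zero_delta(self, rng):
        X = rng.standard_normal((5, 3))
        d = build_cumulative_design(X, np.array([-0.2, 0.1, 0.6]))
        np.testing.assert_array_equal(recover_gamma(np.zeros(3), d), np.zeros(3))

    def test_recover_gamma_rejects_sign_violation(self, rng):
        X = rng.standard_normal((5, 3))
        d = build_cumulative_design(X, np.array([-0.2, 0.1, 0.6]))
        with pytest.raises(ValueError):
            recover_gamma(np.array([0.5, 0.1, 0.1]), d)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=25)
    def test_recovered_gamma_monotone_in_prior_order(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.integers(2, 9)
        z = np.round(rng.uniform(-1, 1, p), 1)  # rounding provokes ties
        if np.all(z == 0):
            return
        X = rng.standard_normal((4, p))
        d = build_cumulative_design(X, z)
        delta = np.where(d.signs < 0, -rng.random(d.n_groups), rng.random(d.n_groups))
        gamma = recover_gamma(delta, d)
        order = np.argsort(z[z != 0], kind="stable")
        np.testing.assert_array_equal(
            np.sort(gamma[z != 0][order]), gamma[z != 0][order]
        )


def _make_instance(rng, n, p, beta, family="gaussian", snr=4.0):
    X = rng.standard_normal((n, p))
    eta = X @ beta
    if family == "gaussian":
        noise_sd = np.sqrt(eta.var() / snr) if eta.var() > 0 else 1.0
        y = eta + noise_sd * rng.standard_normal(n)
    else:
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return GlmDataset(X, y, family)


class TestExponentialCalibration:
    def test_exact_recovery_noiseless(self, rng):
        n, p = 100, 20
        X = rng.standard_normal((n, p))
        z = rng.uniform(-1, 1, p)
        ds = GlmDataset(X, X @ z, "gaussian")
        cal = exponential_calibrate(ds, z)
        assert cal.tau == pytest.approx(1.0)
        assert cal.theta == pytest.approx(1.0, abs=1e-3)

    def test_gamma_factorizes_exactly(self, rng):
        z = rng.uniform(-1, 1, 15)
        ds = _make_instance(rng, 80, 15, np.sign(z) * z**2)
        cal = exponential_calibrate(ds, z)
        expected = cal.theta * np.where(z == 0, 0.0, np.sign(z) * np.abs(z) ** cal.tau)
        np.testing.assert_array_equal(cal.gamma, expected)

    def test_zero_theta_zeroes_gamma(self, rng):
        # prior anti-correlated with the truth: the non-negative slope hits 0
        n, p = 200, 10
        X = rng.standard_normal((n, p))
        beta = np.linspace(1, 0.1, p)
        y = X @ beta + 0.1 * rng.standard_normal(n)
        cal = exponential_calibrate(GlmDataset(X, y, "gaussian"), -beta / beta.max())
        assert cal.theta == 0.0
        np.testing.assert_array_equal(cal.gamma, 0.0)

    def test_allow_negative_inverts(self, rng):
        n, p = 200, 10
        X = rng.standard_normal((n, p))
        beta = np.linspace(1, 0.1, p)
        y = X @ beta + 0.1 * rng.standard_normal(n)
        cal = exponential_calibrate(
            GlmDataset(X, y, "gaussian"), -beta / beta.max(), allow_negative=True
        )
        assert cal.inverted and cal.theta < 0

    def test_degenerate_prior(self, gaussian_data):
        cal = exponential_calibrate(gaussian_data, np.zeros(gaussian_data.p))
        assert cal.degenerate and cal.theta == 0.0
        np.testing.assert_array_equal(cal.gamma, 0.0)

    def test_zero_prior_stays_zero_at_tau_zero(self, rng):
        z = np.array([0.0, 0.5, -0.5, 1.0])
        ds = _make_instance(rng, 60, 4, z)
        cal = exponential_calibrate(ds, z, tau_grid=[0.0])
        assert cal.gamma[0] == 0.0  # 0^0 = 0 convention


class TestIsotonicCalibration:
    def test_constraints_hold(self, rng):
        p = 12
        z = rng.uniform(-1, 1, p)
        z[3] = 0.0
        ds = _make_instance(rng, 80, p, np.sign(z) * np.abs(z) ** 1.5)
        cal = isotonic_calibrate(ds, z)
        assert np.all(cal.gamma[z > 0] >= 0)
        assert np.all(cal.gamma[z < 0] <= 0)
        assert cal.gamma[3] == 0.0
        order = np.argsort(z)
        assert np.all(np.diff(cal.gamma[order]) >= -1e-12)

    @pytest.mark.parametrize("family", ["gaussian", "binomial"])
    def test_matches_order_constrained_oracle(self, rng, family):
        """Direct optimizer on the original sign+order parametrization."""
        n, p = 60, 5
        z = np.array([-0.8, -0.3, 0.2, 0.6, 0.9])
        ds = _make_instance(rng, n, p, z, family=family)
        cal = isotonic_calibrate(ds, z)
        X, y = ds.X, ds.y

        def negloss(t):
            eta = t[0] + X @ t[1:]
            if family == "gaussian":
                return 0.5 * np.mean((y - eta) ** 2)
            return np.mean(np.logaddexp(0.0, eta) - y * eta)

        order = np.argsort(z)
        A = np.zeros((p - 1, 1 + p))
        for i in range(p - 1):
            A[i, 1 + order[i]] = -1.0
            A[i, 1 + order[i + 1]] = 1.0
        cons = [optimize.LinearConstraint(A, 0.0, np.inf)]
        bounds = [(None, None)] + [
            (0, None) if zj > 0 else (None, 0) for zj in z
        ]
        res = optimize.minimize(
            negloss, np.zeros(1 + p), method="SLSQP", bounds=bounds,
            constraints=cons, options={"maxiter": 2000, "ftol": 1e-14},
        )
        np.testing.assert_allclose(cal.gamma, res.x[1:], atol=1e-4)
        assert cal.alpha == pytest.approx(res.x[0], abs=1e-4)

    def test_equal_priors_collapse_to_scalar(self, rng):
        n, p = 70, 6
        z = np.full(p, 0.4)
        ds = _make_instance(rng, n, p, np.full(p, 0.3))
        cal = isotonic_calibrate(ds, z)
        assert np.ptp(cal.gamma) == 0.0
        # equals a one-covariate non-negative regression on the row sum
        v = ds.X.sum(axis=1)
        vc = v - v.mean()
        slope = max(0.0, float(vc @ (ds.y - ds.y.mean()) / (vc @ vc)))
        assert cal.gamma[0] == pytest.approx(slope, abs=1e-5)

    def test_deviance_never_above_intercept_only(self, rng):
        for s in range(5):
            r = np.random.default_rng(s)
            z = r.uniform(-1, 1, 10)
            ds = _make_instance(r, 50, 10, r.standard_normal(10))
            cal = isotonic_calibrate(ds, z)
            null_dev = ds.family.deviance(ds.y, np.full(ds.n, ds.y.mean()))
            assert cal.deviance <= null_dev + 1e-10

    def test_allow_negative_picks_inverted_fit(self, rng):
        n, p = 150, 8
        z = rng.uniform(0.1, 1, p)
        ds = _make_instance(rng, n, p, -z)  # truth anti-monotone in z
        cal = isotonic_calibrate(ds, z, allow_negative=True)
        assert cal.inverted
        assert np.all(cal.gamma <= 1e-12)

    def test_scale_invariance_both_methods(self, rng):
        z = rng.uniform(-1, 1, 10)
        ds = _make_instance(rng, 60, 10, np.sign(z) * z**2)
        for fn in (isotonic_calibrate, exponential_calibrate):
            g1 = fn(ds, z).gamma
            g2 = fn(ds, 3.0 * z).gamma
            np.testing.assert_allclose(g1, g2, atol=1e-10)


class TestCodataFilter:
    def test_intercept_only_fit_not_retained(self, gaussian_data):
        cal = exponential_calibrate(gaussian_data, np.zeros(gaussian_data.p))
        out = filter_codata(gaussian_data, cal)
        assert not out.retained and out.filter_pvalue == 1.0

    def test_power_under_true_prior(self):
        """High-signal instances: the informative source is retained."""
        kept = 0
        N = 100
        for s in range(N):
            rng = np.random.default_rng(3000 + s)
            n, p = 100, 30
            X = rng.standard_normal((n, p))
            beta = np.where(rng.random(p) < 0.2, rng.standard_normal(p), 0.0)
            eta = X @ beta
            sd = eta.std() if eta.std() > 0 else 1.0
            zs = (eta - eta.mean()) / sd
            y = np.sqrt(0.8) * zs + np.sqrt(0.2) * rng.standard_normal(n)
            ds = GlmDataset(X, y, "gaussian")
            scale = np.abs(beta).max()
            z = beta / scale if scale > 0 else beta
            cal = exponential_calibrate(ds, z)
            kept += filter_codata(ds, cal).retained
        assert kept >= 95

    def test_type_one_error_near_nominal(self):
        """Null co-data and null response: ~5% rejections over 400 seeds."""
        rej = 0
        N = 400
        for s in range(N):
            rng = np.random.default_rng(10_000 + s)
            n, p = 50, 20
            ds = GlmDataset(rng.standard_normal((n, p)), rng.standard_normal(n), "gaussian")
            cal = exponential_calibrate(ds, rng.uniform(-1, 1, p))
            rej += filter_codata(ds, cal).retained
        # exact binomial CI at the nominal 5% level must cover the rate
        lo, hi = stats.binom.interval(0.99, N, 0.05)
        assert lo <= rej <= hi

    def test_binomial_filter_uses_deviance_residuals(self, binomial_data):
        z = np.array([1.0, -0.7, 0.0, 0.4, 0.0])
        cal = isotonic_calibrate(binomial_data, z)
        out = filter_codata(binomial_data, cal)
        assert 0.0 <= out.filter_pvalue <= 1.0


class TestScenarioBattery:
    """Six truth-vs-prior shapes: power-law truths favour exponential
    calibration, thresholded/asymmetric truths favour isotonic."""

    @staticmethod
    def _scenario_beta(z, k):
        return {
            1: z,
            2: np.sign(z) * np.sqrt(np.abs(z)),
            3: np.sign(z) * z**2,
            4: (z > 0) * z,
            5: (z > 1).astype(float),
            6: -1.0 * (z <= 0) * np.abs(z) + (z > 0) * z**2,
        }[k]

    def test_battery_ordering_and_tau(self):
        n, p, n_seeds = 200, 500, 20
        mse = {k: {"exp": 0.0, "iso": 0.0} for k in range(1, 7)}
        taus = []
        for s in range(n_seeds):
            rng = np.random.default_rng(1000 + s)
            X = rng.standard_normal((n, p))
            lim = stats.norm.ppf(0.99)
            z = np.clip(rng.standard_normal(p), -lim, lim)
            zr = z / np.abs(z).max()
            for k in range(1, 7):
                beta = self._scenario_beta(z, k)
                eta = X @ beta
                y = eta + np.sqrt(eta.var()) * rng.standard_normal(n)
                ds = GlmDataset(X, y, "gaussian")
                ce = exponential_calibrate(ds, zr)
                ci = isotonic_calibrate(ds, zr)
                mse[k]["exp"] += np.mean((ce.gamma - beta) ** 2) / n_seeds
                mse[k]["iso"] += np.mean((ci.gamma - beta) ** 2) / n_seeds
                if k == 3:
                    taus.append(ce.tau)
        for k in (1, 2, 3):
            assert mse[k]["exp"] < mse[k]["iso"], f"scenario {k}"
        for k in (4, 5, 6):
            assert mse[k]["iso"] < mse[k]["exp"], f"scenario {k}"
        # the quadratic scenario recovers an exponent near 2
        assert 1.6 <= np.mean(taus) <= 2.4
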