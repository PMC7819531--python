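import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from ivdid import (
    SingularDesignError,
    TwoStageLSRegressor,
    ValidationError,
    WeakInstrumentError,
    ols_solve,
    tsls_fit,
    wald_ratio,
)
from tests.conftest import make_random_panel


class TestOlsSolve:
    def test_exact_linear_response_recovered(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = 2.0 + 3.0 * np.arange(10.0)
        fit = ols_solve(X, y)
        assert np.allclose(fit.coef, [2.0, 3.0], atol=1e-12)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)

    def test_intercept_only_gives_mean(self):
        y = np.array([1.0, 2.0, 6.0])
        fit = ols_solve(np.ones((3, 1)), y)
        assert np.isclose(fit.coef[0], y.mean())

    def test_random_instance_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        fit = ols_solve(X, y)
        # brute-force normal equations
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.coef, coef, atol=1e-10)
        resid = y - X @ coef
        sigma2 = resid @ resid / (20 - 4)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        assert np.allclose(fit.cov, cov, atol=1e-10)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        fit = ols_solve(X, y)
        ref = sm.OLS(y, X).fit()
        assert np.allclose(fit.coef, ref.params, atol=1e-10)
        assert np.allclose(np.sqrt(np.diag(fit.cov)), ref.bse, atol=1e-10)

    def test_collinear_columns_named(self):
        X = np.column_stack([np.ones(12), np.arange(12.0), 2 * np.arange(12.0)])
        with pytest.raises(SingularDesignError) as err:
            ols_solve(X, np.arange(12.0), names=["const", "a", "twice_a"])
        assert err.value.collinear  # at least one of the dependent pair named


class TestTwoStageLS:
    def test_noiseless_structural_coefficient_exact(self):
        # x an exact function of z and covariates; y exactly linear in x
        t = np.arange(30.0)
        rows = []
        for period in (0, 1):
            z = ((period == 1) & (t >= 15)).astype(float)
            x = 50.0 - 20.0 * z + 0.3 * t + 2.0 * period
            y = -0.07 * x + 0.1 * t + period
            rows.append(pd.DataFrame({
                "period": period, "t": t, "t2": t**2, "t3": t**3,
                "z": z.astype(int), "x": x, "y": y,
            }))
        panel = pd.concat(rows, ignore_index=True)
        est = tsls_fit(panel)
        assert np.isclose(est.beta, -0.07, atol=1e-10)
        assert np.isclose(est.beta_per100, 7.0, atol=1e-8)

    def test_weak_instrument_raises(self, random_panel):
        panel = random_panel.copy()
        rng = np.random.default_rng(0)
        panel["x"] = rng.normal(100.0, 1.0, len(panel))  # x ignores z
        with pytest.raises(WeakInstrumentError):
            tsls_fit(panel)
        # the ratio oracle guards against a numerically zero denominator:
        # make x an exact function of the covariates
        panel["x"] = 2.0 * panel["t"] + panel["period"]
        with pytest.raises(WeakInstrumentError):
            wald_ratio(panel)

    def test_no_instrument_variation_rejected(self, random_panel):
        panel = random_panel.copy()
        panel["z"] = 0
        with pytest.raises(ValidationError):
            tsls_fit(panel)

    def test_estimate_bracketed_by_interval(self, random_panel):
        est = tsls_fit(random_panel)
        assert est.ci_low <= est.beta <= est.ci_high
        assert est.per100_ci_low <= est.beta_per100 <= est.per100_ci_high
        assert np.isclose(est.beta_per100, -100.0 * est.beta)

    def test_matches_wald_ratio(self, random_panel):
        est = tsls_fit(random_panel)
        assert np.isclose(est.beta, wald_ratio(random_panel), atol=1e-8)

    def test_scaling_contracts(self, random_panel):
        base = tsls_fit(random_panel)
        for c in (2.0, 0.5):
            px = random_panel.copy()
            px["x"] *= c
            est = tsls_fit(px)
            assert np.isclose(est.beta, base.beta / c, rtol=1e-8)
            # per-100 effect per *rescaled* visit unit scales back
            assert np.isclose(est.beta_per100 * c, base.beta_per100, rtol=1e-8)
            py = random_panel.copy()
            py["y"] *= c
            assert np.isclose(tsls_fit(py).beta, base.beta * c, rtol=1e-8)

    def test_translation_leaves_slope(self, random_panel):
        shifted = random_panel.copy()
        shifted["y"] += 500.0
        assert np.isclose(tsls_fit(shifted).beta, tsls_fit(random_panel).beta,
                          atol=1e-9)

    def test_sklearn_protocol(self, random_panel):
        est = TwoStageLSRegressor(se_type="classical")
        params = est.get_params()
        assert params["instrument"] == "z"
        est2 = clone(est).set_params(weak_threshold=3.0)
        est2.fit(random_panel, random_panel["y"])
        assert hasattr(est2, "beta_")
        pred = est2.predict(random_panel)
        assert pred.shape == (len(random_panel),)
        # structural prediction reproduces fitted relation on average
        assert abs((random_panel["y"] - pred).mean()) < 1.0

    def test_newey_west_matches_statsmodels_when_exogenous(self):
        # with x == z the first stage is exact and 2SLS collapses to OLS,
        # so the HAC covariance can be checked against statsmodels
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        n = 80
        t = np.arange(float(n))
        z = (t >= 40).astype(float)
        x = z.copy()
        u = rng.normal(size=n)
        u = u + 0.6 * np.roll(u, 1)  # serially correlated noise
        y = 1.0 - 2.0 * x + 0.05 * t + u
        panel = pd.DataFrame({
            "period": 1, "t": t, "t2": t**2, "t3": t**3,
            "z": z.astype(int), "x": x, "y": y,
        })
        est = TwoStageLSRegressor(
            covariates=("t", "t2", "t3"), se_type="newey_west",
            hac_bandwidth=5,
        ).fit(panel, panel["y"])
        X = np.column_stack([np.ones(n), x, t, t**2, t**3])
        ref = sm.OLS(y, X).fit(cov_type="HAC",
                               cov_kwds={"maxlags": 5, "use_correction": True})
        assert np.isclose(est.beta_, ref.params[1], atol=1e-10)
        assert np.isclose(est.se_, ref.bse[1], rtol=1e-8)

    def test_count_model_requires_error_cov(self, random_panel):
        with pytest.raises(ValidationError, match="error_cov"):
            tsls_fit(random_panel, se_type="count_model")

    def test_count_model_diagonal_matches_sandwich(self, random_panel):
        # hand-computed sandwich with a diagonal error covariance
        n = len(random_panel)
        Sy = np.diag(np.full(n, 4.0))
        Sx = np.zeros((n, n))
        est = tsls_fit(random_panel, se_type="count_model", error_cov=(Sy, Sx))
        W = np.column_stack([
            np.ones(n),
            *[random_panel[c].to_numpy(float) for c in ("z", "period", "t", "t2", "t3")],
        ])
        b1, *_ = np.linalg.lstsq(W, random_panel["x"].to_numpy(float), rcond=None)
        X2 = np.column_stack([
            np.ones(n), W @ b1,
            *[random_panel[c].to_numpy(float) for c in ("period", "t", "t2", "t3")],
        ])
        A = np.linalg.inv(X2.T @ X2)
        cov = A @ (X2.T @ Sy @ X2) @ A
        assert np.isclose(est.se, np.sqrt(cov[1, 1]), rtol=1e-8)


class TestWaldRatio:
    def test_textbook_difference_in_means(self):
        # binary z, no covariates beyond what is constant: build a panel where
        # period/t covariates are balanced out by symmetry is fiddly, so test
        # the estimator definition directly on residualised quantities
        rng = np.random.default_rng(11)
        panel = make_random_panel(rng, n_days=30)
        # textbook check: with covariates projected out, the ratio equals the
        # IV slope cov(y, z~)/cov(x, z~)
        W = np.column_stack([
            np.ones(len(panel)),
            *[panel[c].to_numpy(float) for c in ("period", "t", "t2", "t3")],
        ])
        def res(col):
            v = panel[col].to_numpy(float)
            return v - W @ np.linalg.lstsq(W, v, rcond=None)[0]
        expected = (res("y") @ res("z")) / (res("x") @ res("z"))
        assert np.isclose(wald_ratio(panel), expected, atol=1e-10)

    def test_exact_proportionality_recovered(self, random_panel):
        panel = random_panel.copy()
        panel["y"] = -0.03 * panel["x"]
        assert np.isclose(wald_ratio(panel), -0.03, atol=1e-10)

    def test_equivalence_sweep_with_tsls(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            panel = make_random_panel(rng, n_days=20)
            est = tsls_fit(panel)
            assert np.isclose(est.beta, wald_ratio(panel), atol=1e-8)


class TestClassicalCoverage:
    def test_interval_coverage_under_iid_noise(self):
        """Classical 95% intervals cover the true effect at nominal rate on
        panels generated under the estimator's own iid assumptions."""
        rng = np.random.default_rng(2024)
        beta = -0.05
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            panel = make_random_panel(rng, n_days=30, beta=beta)
            est = tsls_fit(panel)
            hits += est.ci_low <= beta <= est.ci_high
        assert 0.92 <= hits / n_rep <= 0.97
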