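"""Two-stage least squares estimation of the visits -> deaths effect.

The instrumented difference-in-differences design uses the pandemic-onset
indicator (current period on or after the cutoff date) as an instrument for
daily ED attendance. The structural effect of attendance on daily cardiac
deaths is estimated by 2SLS:

* stage 1 regresses the exposure ``x`` on ``[1, z, period, t, t^2, t^3]``;
* stage 2 regresses the outcome ``y`` on the predicted exposure and the same
  covariates.

The stage-2 coefficient on the predicted exposure is the causal effect of one
additional visit on same-lag deaths (expected negative: fewer visits, more
deaths). Reported per-100 effects negate it, following the convention of
"excess deaths per 100 non-attendances".

Standard errors are the proper 2SLS structural-equation errors (residuals
computed with the observed exposure, not its first-stage prediction), either
classical homoskedastic or Newey-West autocorrelation-robust with the kernel
applied within each period's time ordering.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import SingularDesignError, ValidationError, WeakInstrumentError
from .panel import COVARIATES

#: normal critical value for 95% intervals (n ~ 240 makes t vs z negligible)
Z_95 = 1.96


@dataclass(frozen=True)
class OLSFit:
    """Least-squares fit: coefficients, residuals, classical covariance."""

    coef: np.ndarray
    residuals: np.ndarray
    cov: np.ndarray
    sigma2: float
    df_resid: int


def ols_solve(X: np.ndarray, y: np.ndarray, names=None) -> OLSFit:
    """Solve a least-squares problem with classical coefficient covariance.

    Uses a QR factorisation for numerical stability (the cubic time trend
    makes the raw normal equations badly conditioned). The covariance is
    sigma^2 (X'X)^-1 with sigma^2 the residual sum of squares over (n - k).
    Rank deficiency raises :class:`SingularDesignError` naming the collinear
    columns (identified by pivoted-QR diagnostics).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValidationError(f"need more rows ({n}) than columns ({k})")
    names = list(names) if names is not None else [f"col{j}" for j in range(k)]

    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    tol = max(n, k) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    if np.any(diag <= tol):
        # re-factor with column pivoting to name the dependent columns
        from scipy.linalg import qr as qr_pivot

        _, Rp, piv = qr_pivot(X, mode="economic", pivoting=True)
        dp = np.abs(np.diag(Rp))
        bad = [names[piv[j]] for j in range(k) if dp[j] <= tol]
        raise SingularDesignError(
            f"design matrix is rank deficient; collinear columns: {bad}",
            collinear=bad,
        )

    coef = np.linalg.solve(R, Q.T @ y)
    residuals = y - X @ coef
    df = n - k
    sigma2 = float(residuals @ residuals) / df
    Rinv = np.linalg.solve(R, np.eye(k))
    xtx_inv = Rinv @ Rinv.T
    return OLSFit(coef=coef, residuals=residuals, cov=sigma2 * xtx_inv,
                  sigma2=sigma2, df_resid=df)


def _hac_cov(
    X: np.ndarray,
    u: np.ndarray,
    order: np.ndarray,
    blocks: np.ndarray,
    bandwidth: int,
) -> np.ndarray:
    """Newey-West covariance with Bartlett weights, applied per period block.

    ``order`` sorts rows into (block, time) order; lags never cross block
    boundaries because the historical and current periods are independent
    samples. A small-sample n/(n-k) factor is applied.
    """
    n, k = X.shape
    g = (X * u[:, None])[order]
    b = blocks[order]
    S = g.T @ g
    for lag in range(1, int(bandwidth) + 1):
        w = 1.0 - lag / (bandwidth + 1.0)
        same = b[lag:] == b[:-lag]
        gl = g[lag:][same]
        g0 = g[:-lag][same]
        if len(gl):
            cross = g0.T @ gl
            S += w * (cross + cross.T)
    Q, R = np.linalg.qr(X)
    Rinv = np.linalg.solve(R, np.eye(k))
    A = Rinv @ Rinv.T  # (X'X)^-1
    return A @ S @ A * (n / (n - k))


class TwoStageLSRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style just-identified 2SLS regressor.

    Parameters
    ----------
    exposure, instrument : str
        Column names in the fitted frame for the endogenous exposure and the
        binary instrument.
    covariates : tuple of str
        Exogenous adjustment columns, included in both stages (default: the
        period indicator and the linear/squared/cubic day offsets).
    se_type : {"classical", "newey_west", "count_model"}
        Variance estimator for the structural coefficient. ``count_model``
        propagates Poisson weekly-count noise through the known
        disaggregation filter (see :mod:`ivdid.variance`) and requires
        ``error_cov``.
    error_cov : (Sy, Sx) pair of arrays or None
        Row-aligned outcome and exposure error covariances for
        ``se_type="count_model"``; the structural error covariance used is
        Sy + beta^2 Sx.
    hac_bandwidth : int
        Bartlett-kernel bandwidth in days for ``se_type="newey_west"``.
        Within-week disaggregation of weekly deaths ties together daily values
        up to ~20 days apart (a day's value draws on the weekly totals of its
        own and both neighbouring weeks), so the default covers lag 20.
    weak_threshold : float
        Minimum first-stage |coef|/se; below it :class:`WeakInstrumentError`
        is raised rather than returning an unstable ratio.

    Attributes (after ``fit``)
    --------------------------
    beta_ : structural effect of one additional visit on deaths.
    se_, ci_low_, ci_high_ : its standard error and 95% interval.
    beta_per100_, per100_ci_low_, per100_ci_high_ : the negated, x100
        "excess deaths per 100 non-attendances" scale.
    first_stage_coef_, first_stage_se_ : instrument effect on the exposure.
    coef_, feature_names_ : full structural coefficient vector.
    nobs_ : rows used.
    """

    def __init__(
        self,
        exposure: str = "x",
        instrument: str = "z",
        covariates: tuple = COVARIATES,
        se_type: str = "classical",
        hac_bandwidth: int = 21,
        weak_threshold: float = 2.0,
        error_cov=None,
    ):
        self.exposure = exposure
        self.instrument = instrument
        self.covariates = covariates
        self.se_type = se_type
        self.hac_bandwidth = hac_bandwidth
        self.weak_threshold = weak_threshold
        self.error_cov = error_cov

    def _frame(self, X) -> pd.DataFrame:
        X = pd.DataFrame(X)
        needed = [self.exposure, self.instrument, *self.covariates]
        missing = [c for c in needed if c not in X.columns]
        if missing:
            raise ValidationError(f"missing columns in design frame: {missing}")
        return X

    def fit(self, X, y):
        """Fit the two stages. ``X`` holds exposure, instrument, covariates."""
        if self.se_type not in ("classical", "newey_west", "count_model"):
            raise ValidationError(f"unknown se_type {self.se_type!r}")
        if self.se_type == "count_model" and self.error_cov is None:
            raise ValidationError("se_type='count_model' requires error_cov")
        X = self._frame(X)
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValidationError("X and y lengths differ")

        z = X[self.instrument].to_numpy(float)
        x = X[self.exposure].to_numpy(float)
        W = X[list(self.covariates)].to_numpy(float)
        if np.unique(z).size < 2:
            raise ValidationError("instrument has no variation")

        ones = np.ones((len(X), 1))
        X1 = np.hstack([ones, z[:, None], W])
        names1 = ["const", self.instrument, *self.covariates]
        first = ols_solve(X1, x, names1)
        self.first_stage_coef_ = float(first.coef[1])
        self.first_stage_se_ = float(np.sqrt(first.cov[1, 1]))
        if (
            self.first_stage_se_ == 0.0
            and self.first_stage_coef_ == 0.0
        ) or (
            self.first_stage_se_ > 0.0
            and abs(self.first_stage_coef_) / self.first_stage_se_
            < self.weak_threshold
        ):
            raise WeakInstrumentError(
                f"first-stage |coef|/se = "
                f"{abs(self.first_stage_coef_) / max(self.first_stage_se_, 1e-300):.2f}"
                f" below threshold {self.weak_threshold}"
            )

        xhat = X1 @ first.coef
        X2 = np.hstack([ones, xhat[:, None], W])
        names2 = ["const", self.exposure, *self.covariates]
        second = ols_solve(X2, y, names2)
        coef = second.coef

        # proper 2SLS inference: structural residuals use the observed exposure
        X_struct = np.hstack([ones, x[:, None], W])
        u = y - X_struct @ coef
        n, k = X2.shape
        if self.se_type == "classical":
            sigma2 = float(u @ u) / (n - k)
            Q, R = np.linalg.qr(X2)
            Rinv = np.linalg.solve(R, np.eye(k))
            cov = sigma2 * (Rinv @ Rinv.T)
        elif self.se_type == "count_model":
            Sy, Sx = self.error_cov
            Sy = np.asarray(Sy, dtype=float)
            Sx = np.asarray(Sx, dtype=float)
            if Sy.shape != (n, n) or Sx.shape != (n, n):
                raise ValidationError(
                    f"error_cov blocks must be {n}x{n} to match the panel"
                )
            Su = Sy + coef[1] ** 2 * Sx
            Q, R = np.linalg.qr(X2)
            Rinv = np.linalg.solve(R, np.eye(k))
            A = Rinv @ Rinv.T
            cov = A @ (X2.T @ Su @ X2) @ A
        else:
            if "t" in X.columns:
                t_order = X["t"].to_numpy()
            else:
                t_order = np.arange(n)
            if "period" in X.columns:
                blocks = X["period"].to_numpy()
            else:
                blocks = np.zeros(n)
            order = np.lexsort((t_order, blocks))
            cov = _hac_cov(X2, u, order, blocks, self.hac_bandwidth)

        self.coef_ = coef
        self.feature_names_ = names2
        self.beta_ = float(coef[1])
        self.se_ = float(np.sqrt(cov[1, 1]))
        self.cov_ = cov
        self.ci_low_ = self.beta_ - Z_95 * self.se_
        self.ci_high_ = self.beta_ + Z_95 * self.se_
        self.beta_per100_ = -100.0 * self.beta_
        self.per100_ci_low_ = -100.0 * self.ci_high_
        self.per100_ci_high_ = -100.0 * self.ci_low_
        self.resid_ = u
        self.nobs_ = n
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Structural prediction: intercept + beta * observed x + covariates."""
        X = self._frame(X)
        x = X[self.exposure].to_numpy(float)
        W = X[list(self.covariates)].to_numpy(float)
        design = np.hstack([np.ones((len(X), 1)), x[:, None], W])
        return design @ self.coef_


@dataclass(frozen=True)
class IVEstimate:
    """A causal-effect estimate with uncertainty and first-stage diagnostics.

    ``beta`` is deaths per additional visit (negative under the hypothesised
    mechanism); ``beta_per100`` is the reported scale, -100 x beta, i.e.
    excess deaths per 100 non-attendances.
    """

    beta: float
    se: float
    ci_low: float
    ci_high: float
    beta_per100: float
    per100_ci_low: float
    per100_ci_high: float
    first_stage_coef: float
    first_stage_se: float
    lag: int
    n_obs: int
    se_type: str = "classical"

    def __post_init__(self):
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValidationError("interval does not bracket the estimate")


def tsls_fit(
    panel: pd.DataFrame,
    se_type: str = "classical",
    hac_bandwidth: int = 21,
    weak_threshold: float = 2.0,
    error_cov=None,
) -> IVEstimate:
    """Fit the 2SLS design on an analysis panel and return an IVEstimate."""
    est = TwoStageLSRegressor(
        se_type=se_type,
        hac_bandwidth=hac_bandwidth,
        weak_threshold=weak_threshold,
        error_cov=error_cov,
    ).fit(panel, panel["y"])
    return IVEstimate(
        beta=est.beta_,
        se=est.se_,
        ci_low=est.ci_low_,
        ci_high=est.ci_high_,
        beta_per100=est.beta_per100_,
        per100_ci_low=est.per100_ci_low_,
        per100_ci_high=est.per100_ci_high_,
        first_stage_coef=est.first_stage_coef_,
        first_stage_se=est.first_stage_se_,
        lag=int(panel.attrs.get("lag", 0)),
        n_obs=est.nobs_,
        se_type=se_type,
    )


def wald_ratio(panel: pd.DataFrame) -> float:
    """Just-identified IV estimate by the Frisch-Waugh ratio route.

    Residualises x, y and z on the exogenous covariates, then returns
    cov(y~, z~) / cov(x~, z~). Algebraically identical to the 2SLS
    coefficient in the just-identified design; kept as an independent check
    because it shares no code path with :class:`TwoStageLSRegressor`.
    """
    W = np.column_stack(
        [np.ones(len(panel))] + [panel[c].to_numpy(float) for c in COVARIATES]
    )

    def resid(v):
        v = panel[v].to_numpy(float)
        coef, *_ = np.linalg.lstsq(W, v, rcond=None)
        return v - W @ coef

    xt, yt, zt = resid("x"), resid("y"), resid("z")
    n = len(panel)
    denom = float(xt @ zt) / n
    if abs(denom) < 1e-12:
        raise WeakInstrumentError(
            f"residualised cov(x, z) = {denom:.3g} is numerically zero"
        )
    return (float(yt @ zt) / n) / denom
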