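"""Tobit model of annual diameter increment.

Remeasured diameters can shrink (measurement error, bark loss), so annual
increments are treated as left-censored at zero: the latent increment is
``y* = x'beta_g + e``, ``e ~ N(0, sigma_g^2)``, and the observed increment is
``max(0, y*)``.  The design ``x`` is the same canonical vector used for
fecundity (:data:`seedtrend.datamodel.DESIGN_COLUMNS`).

Estimation is by direct likelihood maximization in the Olsen
reparameterization (delta = beta/sigma, h = 1/sigma), in which the Tobit
log-likelihood is globally concave, so the optimizer's stationary point is
the MLE.  Standard errors come from the numerically differentiated observed
information on the natural (beta, log sigma) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.tools import numdiff

from .datamodel import DESIGN_COLUMNS, I_D, I_DG, I_G, I_G2, I_TSP, I_TSUM, I_TSUM2

__all__ = [
    "GrowthCoefficients",
    "TobitRegressor",
    "fit_tobit",
    "predict_increment",
    "growth_partials",
]


@dataclass
class GrowthCoefficients:
    """Fitted Tobit coefficients aligned to the canonical design ordering."""

    beta_g: np.ndarray            # length len(DESIGN_COLUMNS), cm/yr per unit predictor
    sigma_g: float                # latent increment noise scale, cm/yr
    se: Optional[np.ndarray] = None          # SEs for beta_g
    se_log_sigma: Optional[float] = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.beta_g = np.asarray(self.beta_g, dtype=float)
        if self.sigma_g <= 0:
            raise ValueError("sigma_g must be positive")


def _log_ndtr(z: np.ndarray) -> np.ndarray:
    return special.log_ndtr(z)


def _tobit_negloglik_olsen(params: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    # params = (delta, log h); delta = beta/sigma, h = 1/sigma
    p = X.shape[1]
    delta = params[:p]
    h = np.exp(params[p])
    xb = X @ delta
    cens = y <= 0.0
    ll = 0.0
    if np.any(cens):
        ll += float(np.sum(_log_ndtr(-xb[cens])))
    if np.any(~cens):
        r = h * y[~cens] - xb[~cens]
        ll += float(np.sum(-0.5 * r * r - 0.5 * np.log(2 * np.pi) + np.log(h)))
    return -ll


def _tobit_negloglik_natural(params: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    # params = (beta, log sigma); used for observed-information SEs
    p = X.shape[1]
    beta = params[:p]
    sigma = np.exp(params[p])
    olsen = np.concatenate([beta / sigma, [-params[p]]])
    return _tobit_negloglik_olsen(olsen, X, y)


class TobitRegressor(BaseEstimator, RegressorMixin):
    """Left-censored (at zero) Gaussian regression, fit by maximum likelihood.

    Parameters
    ----------
    fit_intercept : bool
        Whether to prepend an intercept column.  The package's own designs
        already carry an intercept, so the default is False.
    tol : float
        Gradient-norm convergence tolerance.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Latent-scale coefficients.
    sigma_ : float
        Latent noise scale.
    se_ : ndarray
        Asymptotic standard errors of ``coef_``.
    loglik_ : float
        Maximized log-likelihood.
    """

    def __init__(self, fit_intercept: bool = False, tol: float = 1e-10, maxiter: int = 500):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.maxiter = maxiter

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TobitRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        n, p = X.shape
        if np.any(y < 0):
            raise ValueError("observed increments must be >= 0 (censored at zero)")
        n_pos = int(np.sum(y > 0))
        if n_pos == 0:
            raise ValueError(
                "all observations are censored at zero: Tobit coefficients are not identifiable"
            )
        if n < 2 * p:
            raise ValueError(f"need at least {2 * p} observations for {p} parameters, got {n}")

        # start from OLS on the uncensored subset
        pos = y > 0
        beta0, *_ = np.linalg.lstsq(X[pos], y[pos], rcond=None)
        resid = y[pos] - X[pos] @ beta0
        s0 = float(np.std(resid)) or 1.0
        x0 = np.concatenate([beta0 / s0, [np.log(1.0 / s0)]])

        res = optimize.minimize(
            _tobit_negloglik_olsen,
            x0,
            args=(X, y),
            method="BFGS",
            jac=None,
            options={"gtol": self.tol, "maxiter": self.maxiter},
        )
        # polish with a Nelder-Mead-free high-precision pass if needed
        if not res.success:
            res = optimize.minimize(
                _tobit_negloglik_olsen, res.x, args=(X, y), method="L-BFGS-B",
                options={"ftol": 1e-14, "gtol": self.tol, "maxiter": self.maxiter},
            )
        delta = res.x[:p]
        h = np.exp(res.x[p])
        sigma = 1.0 / h
        beta = delta * sigma

        natural = np.concatenate([beta, [np.log(sigma)]])
        hess = numdiff.approx_hess(natural, _tobit_negloglik_natural, args=(X, y))
        try:
            cov = np.linalg.inv(hess)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(p + 1, np.nan)

        self.n_features_in_ = p
        self.coef_ = beta
        self.sigma_ = float(sigma)
        self.se_ = se[:p]
        self.se_log_sigma_ = float(se[p])
        self.loglik_ = -float(res.fun)
        self.converged_ = bool(res.success)
        self.n_censored_ = int(n - n_pos)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Expected *observed* increment E[max(0, N(x'b, sigma^2))]."""
        X = np.asarray(X, dtype=float)
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        m = X @ self.coef_
        return _censored_mean(m, self.sigma_)

    def predict_latent(self, X: np.ndarray) -> np.ndarray:
        """Latent linear predictor x'beta_g (may be negative)."""
        X = np.asarray(X, dtype=float)
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X @ self.coef_

    def coefficients(self) -> GrowthCoefficients:
        return GrowthCoefficients(
            beta_g=self.coef_.copy(),
            sigma_g=self.sigma_,
            se=self.se_.copy(),
            se_log_sigma=self.se_log_sigma_,
            converged=self.converged_,
        )


def fit_tobit(
    increments: Sequence[float], designs: np.ndarray, **kwargs
) -> GrowthCoefficients:
    """Fit the Tobit growth model; thin wrapper over :class:`TobitRegressor`."""
    est = TobitRegressor(**kwargs).fit(np.asarray(designs, float), np.asarray(increments, float))
    return est.coefficients()


def _censored_mean(m: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return np.maximum(np.asarray(m, float), 0.0)
    z = np.asarray(m, float) / sigma
    return np.asarray(m, float) * stats.norm.cdf(z) + sigma * stats.norm.pdf(z)


def predict_increment(coefficients: GrowthCoefficients, design: np.ndarray) -> float:
    """Expected observed increment for one design vector (cm/yr, >= 0)."""
    m = float(np.asarray(design, float) @ coefficients.beta_g)
    return float(_censored_mean(np.array([m]), coefficients.sigma_g)[0])


def growth_partials(
    coefficients: GrowthCoefficients, design: np.ndarray
) -> Dict[str, float]:
    """Partial derivatives of the latent growth predictor.

    Returned per underlying variable (not per design column): quadratic and
    interaction columns are folded into the variable they derive from, e.g.
    d g / d Tsum = beta_Tsum + 2 beta_Tsum2 * Tsum.  Keys: 'tsp', 'tsum',
    'deficit', 'diam', 'shade'.
    """
    x = np.asarray(design, dtype=float)
    b = coefficients.beta_g
    tsum = x[I_TSUM]
    g = x[I_G]
    d = x[I_D]
    return {
        "tsp": float(b[I_TSP]),
        "tsum": float(b[I_TSUM] + 2.0 * b[I_TSUM2] * tsum),
        "deficit": float(b[I_D] + b[I_DG] * g),
        "diam": float(b[I_G] + 2.0 * b[I_G2] * g + b[I_DG] * d),
        "shade": float(b[3]),
    }
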