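"""Random-intercept GLMM by Gauss-Hermite quadrature.

Fits models of the form

    g(E[y_ij]) = x_ij' beta + b_i,   b_i ~ N(0, sigma^2)

for a binomial (logit link) or negative-binomial (NB2, log link) response,
with a single grouping factor.  The marginal log-likelihood integrates the
random intercept out with Gauss-Hermite quadrature and is maximised with
L-BFGS-B over (beta, log sigma[, log alpha]).  Standard errors come from the
inverse of a numerically differentiated Hessian at the optimum.

This deliberately small fitter covers the one structure the pipeline needs —
random intercepts per participant — rather than general mixed models.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import gammaln, logsumexp
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess

__all__ = ["GlmmResult", "SeparationError", "fit_glmm"]

_LOG_SIGMA_MIN, _LOG_SIGMA_MAX = np.log(1e-6), np.log(50.0)
_LOG_ALPHA_MIN, _LOG_ALPHA_MAX = np.log(1e-8), np.log(1e3)


class SeparationError(ValueError):
    """Raised when a binary outcome is completely separated (degenerate MLE)."""


@dataclass
class GlmmResult:
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray          # covariance of beta only
    sigma: float             # random-intercept SD
    alpha: float | None      # NB2 dispersion (None for binomial)
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int


def _nb2_loglik(y, mu, alpha):
    # NB2: var = mu + alpha mu^2; alpha -> 0 recovers Poisson
    size = 1.0 / alpha
    return (
        gammaln(y + size)
        - gammaln(size)
        - gammaln(y + 1.0)
        + size * (np.log(size) - np.log(size + mu))
        + y * (np.log(mu) - np.log(size + mu))
    )


def fit_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    family: str,
    n_quad: int = 15,
    maxiter: int = 500,
) -> GlmmResult:
    """Fit a random-intercept GLMM.  ``family`` is ``"binomial"`` or
    ``"negbin"``."""
    if family not in ("binomial", "negbin"):
        raise ValueError(f"unsupported family {family!r}")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X disagree in length")
    codes, uniques = pd.factorize(np.asarray(groups))
    n_groups = len(uniques)

    if family == "binomial":
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binomial outcome must be 0/1")
        if y.min() == y.max():
            raise SeparationError("outcome is constant (all 0 or all 1)")
    else:
        if (y < 0).any() or not np.allclose(y, np.round(y)):
            raise ValueError("count outcome must be nonnegative integers")
        if y.max() == 0:
            raise ValueError("all-zero count outcome; rate model undefined")

    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)  # probabilists'
    log_w = np.log(weights / np.sqrt(2.0 * np.pi))

    def negloglik(params):
        beta = params[:p]
        sigma = np.exp(params[p])
        eta0 = X @ beta
        # (n, Q) linear predictor with b = sigma * node
        eta = eta0[:, None] + sigma * nodes[None, :]
        if family == "binomial":
            # y*eta - log1p(exp(eta)), stable via logaddexp
            ll_obs = y[:, None] * eta - np.logaddexp(0.0, eta)
        else:
            alpha = np.exp(params[p + 1])
            mu = np.exp(np.clip(eta, -30.0, 30.0))
            ll_obs = _nb2_loglik(y[:, None], mu, alpha)
        # sum within groups for each node
        grp_ll = np.zeros((n_groups, n_quad))
        np.add.at(grp_ll, codes, ll_obs)
        total = logsumexp(grp_ll + log_w[None, :], axis=1).sum()
        return -total

    # starting values from the corresponding fixed-effects GLM
    if family == "binomial":
        glm = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            start_beta = glm.fit(maxiter=100).params
        except Exception:
            start_beta = np.zeros(p)
        if not np.all(np.isfinite(start_beta)) or np.abs(start_beta).max() > 15:
            raise SeparationError("complete separation in binary outcome")
        x0 = np.concatenate([start_beta, [np.log(0.3)]])
        bounds = [(None, None)] * p + [(_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)]
    else:
        glm = sm.GLM(y, X, family=sm.families.Poisson())
        try:
            start_beta = glm.fit(maxiter=100).params
        except Exception:
            start_beta = np.zeros(p)
        if not np.all(np.isfinite(start_beta)):
            start_beta = np.zeros(p)
        x0 = np.concatenate([start_beta, [np.log(0.3)], [np.log(0.3)]])
        bounds = [(None, None)] * p + [
            (_LOG_SIGMA_MIN, _LOG_SIGMA_MAX),
            (_LOG_ALPHA_MIN, _LOG_ALPHA_MAX),
        ]

    res = optimize.minimize(
        negloglik, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
    )
    params = res.x
    beta = params[:p]
    sigma = float(np.exp(params[p]))
    alpha = float(np.exp(params[p + 1])) if family == "negbin" else None

    # covariance of the fixed effects from the full observed information
    cov_beta, se = _beta_covariance(negloglik, params, p)
    return GlmmResult(
        beta=beta,
        se=se,
        cov=cov_beta,
        sigma=sigma,
        alpha=alpha,
        loglik=-float(res.fun),
        converged=bool(res.success),
        n_obs=n,
        n_groups=n_groups,
    )


def _beta_covariance(negloglik, params, p):
    try:
        hess = approx_hess(params, negloglik)
        # variance parameters can sit on their bounds; fall back to the
        # beta block if the full information matrix is singular there
        try:
            cov_full = np.linalg.inv(hess)
            cov_beta = cov_full[:p, :p]
            if np.any(np.diag(cov_beta) <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            cov_beta = np.linalg.pinv(hess[:p, :p])
        se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))
    except Exception:
        cov_beta = np.full((p, p), np.nan)
        se = np.full(p, np.nan)
    return cov_beta, se
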