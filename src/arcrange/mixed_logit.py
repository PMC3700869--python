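"""Maximum-likelihood logistic regression with a per-group random intercept.

Model: y_ij ~ Bernoulli(p_ij), logit(p_ij) = x_ij' beta + b_i, b_i ~ N(0, s^2).

The marginal log-likelihood integrates the random intercept out with adaptive
Gauss-Hermite quadrature: for each group the integrand is recentred at its
mode (found by a scalar Newton iteration) and rescaled by the curvature there,
which keeps the quadrature accurate even for large clusters where the
integrand is sharply peaked. Parameters (beta, log s) are optimized with
L-BFGS-B; standard errors come from the inverse of the numerically
differentiated Hessian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_hess1

_LOG_SIGMA_MIN = -10.0  # effectively sigma = 0


@dataclass
class MixedLogitResult:
    params: np.ndarray  # beta
    sigma: float  # random-intercept SD
    bse: np.ndarray  # SE of beta
    llf: float
    converged: bool
    exog_names: list
    n_groups: int
    nobs: int


def _log1pexp(v):
    """log(1 + exp(v)) without overflow."""
    out = np.empty_like(v)
    big = v > 30
    out[big] = v[big]
    out[~big] = np.log1p(np.exp(v[~big]))
    return out


def _group_loglik(eta, y, sigma, nodes, weights):
    """Marginal log-likelihood of one group by adaptive Gauss-Hermite.

    eta: fixed-effect linear predictor of the group's rows.
    """
    if sigma < 1e-8:
        return float((y * eta - _log1pexp(eta)).sum())

    def h_and_derivs(b):
        lin = eta + b
        p = 1.0 / (1.0 + np.exp(-lin))
        h = (y * lin - _log1pexp(lin)).sum() - 0.5 * b * b / (sigma * sigma)
        g = (y - p).sum() - b / (sigma * sigma)
        hess = -(p * (1 - p)).sum() - 1.0 / (sigma * sigma)
        return h, g, hess

    b = 0.0
    for _ in range(50):  # Newton for the integrand mode
        _, g, hess = h_and_derivs(b)
        step = -g / hess
        b += step
        if abs(step) < 1e-10:
            break
    _, _, hess = h_and_derivs(b)
    scale = 1.0 / np.sqrt(-hess)
    # integral of exp(h(b)) db ~ scale * sum_k w_k exp(h(b + scale*z_k) + z_k^2/2)
    pts = b + scale * nodes
    lin = eta[:, None] + pts[None, :]
    logdens = (y[:, None] * lin - _log1pexp(lin)).sum(0) - 0.5 * pts * pts / (
        sigma * sigma
    )
    logterms = logdens + 0.5 * nodes * nodes + np.log(weights) + np.log(scale)
    m = logterms.max()
    log_integral = m + np.log(np.exp(logterms - m).sum())
    return float(log_integral - 0.5 * np.log(2 * np.pi) - np.log(sigma))


def loglik(theta, y, X, group_slices, nodes, weights):
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    eta = X @ beta
    total = 0.0
    for sl in group_slices:
        total += _group_loglik(eta[sl], y[sl], sigma, nodes, weights)
    return total


def fit_mixed_logit(
    y,
    X,
    groups,
    exog_names=None,
    n_quad: int = 15,
    start_params=None,
    maxiter: int = 200,
) -> MixedLogitResult:
    """Fit the random-intercept logistic model by adaptive quadrature ML.

    y: 0/1 response; X: design matrix (include the intercept column);
    groups: group label per row. Rows are re-sorted by group internally.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="stable")
    y, X, groups = y[order], X[order], groups[order]
    _, starts = np.unique(groups, return_index=True)
    bounds_idx = list(starts) + [len(y)]
    group_slices = [
        slice(bounds_idx[i], bounds_idx[i + 1]) for i in range(len(starts))
    ]
    # probabilists' rule: integral g(z) e^{-z^2/2} dz ~ sum w_k g(z_k);
    # _group_loglik applies the exp(z^2/2) correction to the integrand.
    nodes, weights = hermegauss(n_quad)

    if start_params is None:
        import statsmodels.api as sm

        with np.errstate(all="ignore"):
            logit0 = sm.Logit(y, X).fit(disp=0, maxiter=100)
        start_params = np.r_[logit0.params, np.log(0.5)]

    def negll(theta):
        return -loglik(theta, y, X, group_slices, nodes, weights)

    res = minimize(
        negll,
        start_params,
        method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1] + [(_LOG_SIGMA_MIN, 5.0)],
        options={"maxiter": maxiter},
    )
    theta = res.x
    hess = approx_hess1(theta, negll)
    try:
        cov = np.linalg.inv(hess)
        bse = np.sqrt(np.clip(np.diag(cov)[:-1], 0, None))
    except np.linalg.LinAlgError:
        bse = np.full(X.shape[1], np.nan)
    return MixedLogitResult(
        params=theta[:-1],
        sigma=float(np.exp(theta[-1])),
        bse=bse,
        llf=-float(res.fun),
        converged=bool(res.success),
        exog_names=list(exog_names) if exog_names is not None else None,
        n_groups=len(starts),
        nobs=len(y),
    )
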