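"""Random-intercept logistic regression by Gauss-Hermite quadrature.

Marginal maximum likelihood for a logistic model with one Gaussian random
intercept per group: the per-group likelihood integral over the intercept
is evaluated with Gauss-Hermite quadrature (25 nodes by default, ample for
the small within-family cluster sizes and moderate intercept variances this
package deals in), and the marginal log-likelihood is maximized over the
fixed effects and log random-intercept SD with BFGS.  Standard errors come
from the inverse numerical Hessian at the optimum.  Everything is
deterministic given the data and starting values (which are the plain
logistic fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import logsumexp
from statsmodels.tools.numdiff import approx_hess1


@dataclass
class GHLogitFit:
    params: np.ndarray  # fixed effects
    bse: np.ndarray
    re_var: float  # random-intercept variance
    llf: float
    converged: bool
    singular: bool  # random intercept estimated at (numerically) zero
    separation: bool


def _group_starts(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort order and reduceat start indices for the group structure."""
    order = np.argsort(groups, kind="stable")
    sorted_groups = groups[order]
    starts = np.flatnonzero(np.r_[True, sorted_groups[1:] != sorted_groups[:-1]])
    return order, starts


def fit_logistic_gh(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    n_nodes: int = 25,
) -> GHLogitFit:
    """Fit y ~ X with a per-group Gaussian random intercept.

    ``X`` must include its own intercept column.  Groups may be any
    hashable labels; singletons are allowed (they still contribute to the
    variance component through the marginal likelihood).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("binary outcome must be coded 0 (control) or 1 (case)")
    order, starts = _group_starts(groups)
    ys, Xs = y[order], X[order]
    sign = 1.0 - 2.0 * ys  # log-lik of obs: -log(1 + exp(sign * eta))

    nodes, weights = hermgauss(n_nodes)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)

    glm = sm.GLM(ys, Xs, family=sm.families.Binomial())
    separation = False
    try:
        glm_res = glm.fit(maxiter=200)
        beta0 = np.asarray(glm_res.params)
        if not np.isfinite(beta0).all() or np.abs(beta0).max() > 30:
            separation = True
            beta0 = np.clip(np.nan_to_num(beta0), -5, 5)
    except Exception:
        separation = True
        beta0 = np.zeros(X.shape[1])

    def nll(params: np.ndarray) -> float:
        beta, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
        eta = Xs @ beta
        z = sign[:, None] * (eta[:, None] + np.sqrt(2.0) * sigma * nodes[None, :])
        ll_obs = -np.logaddexp(0.0, z)
        ll_group = np.add.reduceat(ll_obs, starts, axis=0)
        return -float(logsumexp(ll_group + log_w[None, :], axis=1).sum())

    x0 = np.r_[beta0, np.log(0.3)]
    res = optimize.minimize(nll, x0, method="BFGS", options={"maxiter": 500, "gtol": 1e-6})
    params = res.x
    re_sd = float(np.exp(params[-1]))
    # boundary: below this the random intercept is indistinguishable from 0
    # and the profile over log-sigma is flat
    singular = re_sd < 1e-2

    if singular:
        # variance component at the boundary: report the plain logistic fit
        glm_res = glm.fit(maxiter=200)
        return GHLogitFit(
            params=np.asarray(glm_res.params),
            bse=np.asarray(glm_res.bse),
            re_var=0.0,
            llf=float(glm_res.llf),
            converged=bool(glm_res.converged),
            singular=True,
            separation=separation,
        )

    hess = approx_hess1(params, nll)
    try:
        cov = np.linalg.inv(hess)
        bse = np.sqrt(np.clip(np.diag(cov)[:-1], 0, None))
        hess_ok = np.isfinite(bse).all()
    except np.linalg.LinAlgError:
        bse = np.full(X.shape[1], np.nan)
        hess_ok = False

    return GHLogitFit(
        params=params[:-1],
        bse=bse,
        re_var=re_sd**2,
        llf=-res.fun,
        converged=bool(res.success and hess_ok),
        singular=False,
        separation=separation,
    )
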