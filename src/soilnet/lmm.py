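"""Random-intercept linear mixed model via profile maximum likelihood.

For a single grouping factor the covariance is V = sigma_e^2 (I + gamma
Z Z'), gamma the ratio of the random-intercept variance to the residual
variance.  For fixed gamma the GLS estimate, the profiled sigma_e^2 and the
log-likelihood are closed-form (per group, (I + gamma J)^{-1} =
I - gamma/(1 + gamma m) J), so the full ML fit reduces to a bounded
one-dimensional optimization over log gamma.  Wald z p-values for the fixed
effects follow the usual large-sample convention.

This is the workhorse behind every mixed fit in the package (correlation
screens, the stability-coupling test, the path-model equations), where
thousands of small fits are run; it agrees with the general-purpose ML
mixed-model implementation in statsmodels, which the test suite uses as the
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["RandomInterceptResult", "fit_random_intercept"]


@dataclass
class RandomInterceptResult:
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    llf: float  # ML log-likelihood
    sigma2_resid: float
    sigma2_group: float
    converged: bool

    @property
    def n_variance_params(self) -> int:
        return 2


def _profile(y: np.ndarray, X: np.ndarray, codes: np.ndarray, n_groups: int,
             gamma: float):
    """GLS at fixed variance ratio gamma; returns (-loglik, beta, cov_factor,
    sigma2)."""
    n = len(y)
    m = np.bincount(codes, minlength=n_groups).astype(float)
    shrink = gamma / (1.0 + gamma * m)  # per group

    def winv(v: np.ndarray) -> np.ndarray:
        if v.ndim == 1:
            gs = np.bincount(codes, v, n_groups)
            return v - shrink[codes] * gs[codes]
        out = np.empty_like(v)
        for j in range(v.shape[1]):
            gs = np.bincount(codes, v[:, j], n_groups)
            out[:, j] = v[:, j] - shrink[codes] * gs[codes]
        return out

    WX = winv(X)
    Wy = winv(y)
    xtwx = X.T @ WX
    beta = np.linalg.solve(xtwx, X.T @ Wy)
    resid = y - X @ beta
    rss = float(resid @ winv(resid))
    sigma2 = rss / n
    logdet = float(np.log1p(gamma * m).sum())
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdet)
    return -ll, beta, np.linalg.inv(xtwx), sigma2


def fit_random_intercept(y, X, groups) -> RandomInterceptResult:
    """ML fit of y = X beta + u_group + e with a scalar random intercept.

    ``X`` must already contain the intercept column.  Degenerate groupings
    (one group) collapse to ordinary least squares (gamma = 0).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, uniques = pd.factorize(np.asarray(groups))
    n_groups = len(uniques)

    def neg_ll(log_gamma: float) -> float:
        return _profile(y, X, codes, n_groups, np.exp(log_gamma))[0]

    best_log_gamma = -np.inf  # gamma -> 0: OLS boundary
    converged = True
    if n_groups >= 2:
        res = optimize.minimize_scalar(
            neg_ll, bounds=(-12.0, 8.0), method="bounded",
            options={"xatol": 1e-6},
        )
        converged = bool(res.success)
        # accept the interior optimum only if it beats the OLS boundary
        if res.fun < _profile(y, X, codes, n_groups, 0.0)[0]:
            best_log_gamma = float(res.x)
    gamma = np.exp(best_log_gamma) if np.isfinite(best_log_gamma) else 0.0
    nll, beta, cov_factor, sigma2 = _profile(y, X, codes, n_groups, gamma)
    cov = sigma2 * cov_factor
    bse = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(bse > 0, beta / bse, np.inf)
    pvalues = 2 * stats.norm.sf(np.abs(z))
    return RandomInterceptResult(
        params=beta,
        bse=bse,
        pvalues=pvalues,
        llf=-nll,
        sigma2_resid=sigma2,
        sigma2_group=sigma2 * gamma,
        converged=converged,
    )
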