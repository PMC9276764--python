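"""Weighted random-intercept linear mixed model, fitted by maximum likelihood.

The model is y = X beta + b_group + eps with b_group ~ N(0, tau^2) and
eps_i ~ N(0, sigma^2 / w_i) for known observation weights w_i (here
proportional to the Pool-seq effective sample size N_eff).  Fits use plain
ML (not REML) so likelihood-ratio tests on fixed effects are valid.

The likelihood is profiled analytically over beta and sigma^2, leaving a
one-dimensional optimization over the variance ratio lambda = tau^2/sigma^2;
per-group matrix algebra is closed-form via the rank-one Woodbury identity,
which keeps per-locus fits cheap enough to run genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar


@dataclass
class LMMFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    tau2: float
    loglik: float
    converged: bool


def _profile_loglik(lam: float, y, X, weights, group_slices):
    """Profile log-likelihood at variance ratio lam; returns
    (loglik, beta, cov_beta_unscaled, sigma2)."""
    n, p = X.shape
    A = np.zeros((p, p))
    c = np.zeros(p)
    logdet = 0.0
    # accumulate X' M^-1 X etc. with M_g^-1 = W_g - lam w w' / (1 + lam S_w)
    parts = []
    for sl in group_slices:
        w = weights[sl]
        Xg = X[sl]
        yg = y[sl]
        S = w.sum()
        shrink = lam / (1.0 + lam * S)
        Xw = Xg.T @ w  # X' w
        yw = yg @ w
        A += (Xg * w[:, None]).T @ Xg - shrink * np.outer(Xw, Xw)
        c += Xg.T @ (w * yg) - shrink * Xw * yw
        logdet += -np.log(w).sum() + np.log1p(lam * S)
        parts.append((sl, w, S, shrink, yw))
    try:
        beta = np.linalg.solve(A, c)
    except np.linalg.LinAlgError:
        return -np.inf, None, None, np.nan
    rss = 0.0
    for sl, w, S, shrink, yw in parts:
        r = y[sl] - X[sl] @ beta
        rw = r @ w
        rss += (r * w) @ r - shrink * rw * rw
    if rss <= 0:
        return -np.inf, beta, A, 0.0
    sigma2 = rss / n
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return ll, beta, A, sigma2


def fit_weighted_lmm(y, X, groups, weights) -> LMMFit:
    """ML fit of the weighted random-intercept model.

    ``groups`` is any array of group labels; ``weights`` are inverse relative
    residual variances.  Raises ``np.linalg.LinAlgError``-free: a singular
    design yields an LMMFit with NaN loglik (caller flags the locus).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    weights = np.asarray(weights, dtype=float)
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="stable")
    y, X, weights, groups = y[order], X[order], weights[order], groups[order]
    bounds = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1], True])
    group_slices = [slice(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]

    def neg(u):
        ll, *_ = _profile_loglik(np.exp(u), y, X, weights, group_slices)
        return -ll

    res = minimize_scalar(neg, bounds=(-14.0, 14.0), method="bounded",
                          options={"xatol": 1e-6})
    ll_hat, beta, A, sigma2 = _profile_loglik(
        np.exp(res.x), y, X, weights, group_slices
    )
    ll0, beta0, A0, sigma20 = _profile_loglik(0.0, y, X, weights, group_slices)
    if ll0 >= ll_hat:  # boundary solution tau^2 = 0
        ll_hat, beta, A, sigma2, lam = ll0, beta0, A0, sigma20, 0.0
    else:
        lam = float(np.exp(res.x))
    if beta is None or not np.isfinite(ll_hat):
        p = X.shape[1]
        return LMMFit(np.full(p, np.nan), np.full((p, p), np.nan),
                      np.nan, np.nan, np.nan, False)
    cov_beta = sigma2 * np.linalg.inv(A)
    return LMMFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2=float(sigma2),
        tau2=float(lam * sigma2),
        loglik=float(ll_hat),
        converged=bool(res.success),
    )
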