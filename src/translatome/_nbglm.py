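"""Vectorised negative-binomial GLM machinery shared by diffexp and occupancy.

All fits use a log link with a per-sample offset (log effective library size)
and are batched across genes: for G genes, n samples and p coefficients the
IRLS normal equations are solved as a stack of G p x p systems.  Dispersion
phi parameterises Var(Y) = mu + phi mu^2; phi -> 0 recovers Poisson.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import gammaln

_MIN_MU = 1e-10
_MAX_ETA = 50.0


@dataclasses.dataclass
class GLMFit:
    beta: np.ndarray        # (G, p)
    mu: np.ndarray          # (G, n)
    deviance: np.ndarray    # (G,)
    converged: np.ndarray   # (G,) bool


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Per-gene NB log-likelihood summed over samples; y, mu are (G, n)."""
    mu = np.maximum(mu, _MIN_MU)
    phi = np.maximum(np.asarray(phi, dtype=float), 1e-12)
    if phi.ndim == 1:
        phi = phi[:, None]
    r = 1.0 / phi
    # r*log(r/(mu+r)) as -r*log1p(mu/r): stable for tiny phi (huge r)
    ll = (gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
          + y * (np.log(mu) - np.log(mu + r))
          - r * np.log1p(mu / r))
    return ll.sum(axis=1)


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """2 * (loglik at saturated mu=y minus loglik at mu); (G,) over samples."""
    mu = np.maximum(mu, _MIN_MU)
    phi = np.maximum(np.asarray(phi, dtype=float), 1e-12)
    if phi.ndim == 1:
        phi = phi[:, None]
    r = 1.0 / phi
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    # (y+r)*log((y+r)/(mu+r)) via log1p((y-mu)/(mu+r)): avoids cancellation
    # in the Poisson limit where r dwarfs y and mu
    term2 = (y + r) * np.log1p((y - mu) / (mu + r))
    return 2.0 * (term1 - term2).sum(axis=1)


def fit_glm(y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: np.ndarray | float,
            max_iter: int = 50, tol: float = 1e-8) -> GLMFit:
    """Batched NB GLM fit by Fisher scoring with deviance step-halving.

    Parameters
    ----------
    y : (G, n) counts
    X : (n, p) design matrix
    offset : (n,) or (G, n) log effective library sizes
    phi : scalar or (G,) dispersion
    """
    y = np.asarray(y, dtype=float)
    G, n = y.shape
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (G, n))
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (G,)).copy()

    # init: weighted least squares on log(y + 1/6 mean) pseudo-data
    mu = y + np.maximum(y.mean(axis=1, keepdims=True), 1.0) / 6.0
    eta = np.log(mu) - offset
    XtX = X.T @ X
    beta = np.linalg.solve(XtX[None, :, :].repeat(G, axis=0),
                           np.einsum("np,gn->gp", X, eta)[..., None])[..., 0]
    eta = np.einsum("np,gp->gn", X, beta)
    mu = np.exp(np.clip(eta + offset, -_MAX_ETA, _MAX_ETA))
    dev = nb_deviance(y, mu, phi_arr)
    converged = np.zeros(G, dtype=bool)

    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        w = mu / (1.0 + phi_arr[:, None] * mu)            # Fisher weights
        z = eta + (y - mu) / np.maximum(mu, _MIN_MU)      # working response
        A = np.einsum("ni,gn,nj->gij", X, w[active], X)
        b = np.einsum("ni,gn->gi", X, (w * z)[active])
        # ridge jitter keeps near-singular systems (all-zero groups) solvable
        A += 1e-8 * np.eye(p)[None, :, :]
        beta_new = np.linalg.solve(A, b[..., None])[..., 0]

        step = np.zeros_like(beta)
        step[active] = beta_new - beta[active]
        frac = np.ones((G, 1))
        for _half in range(15):
            eta_try = np.einsum("np,gp->gn", X, beta + frac * step)
            mu_try = np.exp(np.clip(eta_try + offset, -_MAX_ETA, _MAX_ETA))
            dev_try = nb_deviance(y, mu_try, phi_arr)
            worse = active & (dev_try > dev + 1e-10)
            if not worse.any():
                break
            frac[worse] *= 0.5
        beta = beta + frac * step
        eta = np.einsum("np,gp->gn", X, beta)
        mu = np.exp(np.clip(eta + offset, -_MAX_ETA, _MAX_ETA))
        dev_new = nb_deviance(y, mu, phi_arr)
        newly = active & (np.abs(dev - dev_new) < tol * (np.abs(dev_new) + 1.0))
        converged |= newly
        dev = dev_new

    return GLMFit(beta=beta, mu=mu, deviance=dev, converged=converged)


def cox_reid_apl(y: np.ndarray, X: np.ndarray, offset: np.ndarray,
                 phi: np.ndarray | float) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood of phi per gene.

    APL(phi) = loglik(beta_hat(phi); phi) - 1/2 log det(X' W X), the standard
    adjustment for estimating the p regression nuisance parameters.
    """
    G = y.shape[0]
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (G,))
    fit = fit_glm(y, X, offset, phi_arr)
    ll = nb_loglik(y, fit.mu, phi_arr)
    w = fit.mu / (1.0 + phi_arr[:, None] * fit.mu)
    A = np.einsum("ni,gn,nj->gij", X, w, X)
    A += 1e-10 * np.eye(X.shape[1])[None, :, :]
    _, logdet = np.linalg.slogdet(A)
    return ll - 0.5 * logdet


def lrt(y: np.ndarray, X_full: np.ndarray, X_null: np.ndarray, offset: np.ndarray,
        phi: np.ndarray | float):
    """Likelihood-ratio test of nested NB GLMs; returns (stat, full_fit, null_fit).

    The statistic is the deviance difference (equivalently twice the log-
    likelihood difference) clipped at zero, chi-square with
    rank(X_full) - rank(X_null) df under the null.
    """
    full = fit_glm(y, X_full, offset, phi)
    null = fit_glm(y, X_null, offset, phi)
    stat = np.maximum(null.deviance - full.deviance, 0.0)
    return stat, full, null
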