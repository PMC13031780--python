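"""Logistic mixed-effects regression via the Laplace approximation.

Fits binomial-logit models with Gaussian random effects grouped by one
clustering factor (participants), supporting a random intercept, independent
intercept + slope, or correlated intercept + slope.

The marginal log-likelihood integrates the random effects out of the joint
likelihood; the integral per group is approximated by Laplace's method around
the posterior mode.  Random effects are parameterized through the Cholesky
factor ``L`` of their covariance (``b_g = L u_g`` with ``u_g ~ N(0, I)``), so
boundary fits (zero variances) remain well defined:

    ll = sum_g [ ll_g(L u_g*) - |u_g*|^2 / 2 - log det(L' F_g L + I) / 2 ]

where ``u_g*`` is the per-group penalized mode and ``F_g`` the Fisher
information of the conditional logistic likelihood at the mode.  The inner
mode search is a damped Newton iteration vectorized across groups; the outer
problem maximizes the Laplace log-likelihood over fixed effects and the free
elements of ``L`` with L-BFGS-B (diagonal of ``L`` bounded at zero).

Standard errors of the fixed effects are computed from the numerically
differentiated observed information at the optimum, holding the variance
parameters fixed at their estimates (the usual GLMM convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import expit

from .errors import SeparationError

__all__ = ["GLMMResult", "fit_logistic_glmm"]

_STRUCTURES = ("full", "diag", "intercept")


@dataclass
class GLMMResult:
    """Raw output of :func:`fit_logistic_glmm`."""

    beta: np.ndarray            # fixed effects
    se: np.ndarray              # their standard errors (conditional on theta)
    cov_beta: np.ndarray
    L: np.ndarray               # Cholesky factor of the RE covariance
    cov_re: np.ndarray          # L @ L.T
    loglik: float               # Laplace marginal log-likelihood
    aic: float
    converged: bool
    n_obs: int
    n_groups: int
    structure: str
    modes: np.ndarray           # posterior modes of b_g = L u_g, shape (G, d)
    n_iter: int


def _check_separation(y: np.ndarray, X: np.ndarray) -> None:
    if y.min() == y.max():
        raise SeparationError(
            "all outcomes identical: the fixed effects are not identifiable"
        )
    # a binary covariate whose levels have constant outcomes separates perfectly
    for j in range(X.shape[1]):
        col = X[:, j]
        levels = np.unique(col)
        if len(levels) == 2:
            for lev in levels:
                yl = y[col == lev]
                if len(yl) > 0 and yl.min() == yl.max():
                    raise SeparationError(
                        f"complete separation: outcomes constant within a level "
                        f"of fixed-effect column {j}"
                    )


def _theta_to_L(theta: np.ndarray, d: int, structure: str) -> np.ndarray:
    L = np.zeros((d, d))
    if structure == "full":
        idx = 0
        for i in range(d):
            for j in range(i + 1):
                L[i, j] = theta[idx]
                idx += 1
    else:  # diag / intercept
        L[np.diag_indices(d)] = theta
    return L


def _n_theta(d: int, structure: str) -> int:
    return d * (d + 1) // 2 if structure == "full" else d


def _init_beta(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Plain logistic regression by Newton iteration (deterministic init)."""
    beta = np.zeros(X.shape[1])
    for _ in range(25):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.clip(beta, -10, 10)


def fit_logistic_glmm(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    groups: np.ndarray,
    structure: str = "full",
    max_outer: int = 500,
    gtol: float = 1e-6,
) -> GLMMResult:
    """Fit ``y ~ X beta + Z b_g`` with ``b_g ~ N(0, Sigma)`` per group.

    Parameters
    ----------
    y : (n,) 0/1 outcomes
    X : (n, k) fixed-effect design (include the constant column yourself)
    Z : (n, d) random-effect design
    groups : (n,) group labels (any hashable values)
    structure : "full" (correlated), "diag" (independent) or "intercept"
        (first Z column only)
    """
    if structure not in _STRUCTURES:
        raise ValueError(f"unknown random-effect structure {structure!r}")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if structure == "intercept":
        Z = Z[:, :1]
    d = Z.shape[1]
    _check_separation(y, X)

    # sort rows by group so per-group reductions are contiguous
    codes = np.unique(np.asarray(groups), return_inverse=True)[1]
    order = np.argsort(codes, kind="stable")
    y_s, X_s, Z_s, g_s = y[order], X[order], Z[order], codes[order]
    G = int(g_s[-1]) + 1
    starts = np.searchsorted(g_s, np.arange(G))
    n, k = X_s.shape

    # precomputed per-row outer products of Z for the Fisher blocks
    ZZ = Z_s[:, :, None] * Z_s[:, None, :]          # (n, d, d)

    def seg_sum(a: np.ndarray) -> np.ndarray:
        return np.add.reduceat(a, starts, axis=0)

    state = {"u": np.zeros((G, d))}

    def inner(beta: np.ndarray, L: np.ndarray, u0: np.ndarray):
        """Per-group penalized mode of u given (beta, L); damped Newton."""
        xb = X_s @ beta
        u = u0.copy()
        eye = np.eye(d)

        def penalized(u_):
            b = u_ @ L.T
            eta = xb + np.einsum("nd,nd->n", Z_s, b[g_s])
            # log-lik per row: y*eta - log(1+e^eta), stable via logaddexp
            ll_rows = y_s * eta - np.logaddexp(0.0, eta)
            return seg_sum(ll_rows) - 0.5 * np.einsum("gd,gd->g", u_, u_), eta

        obj, eta = penalized(u)
        for it in range(50):
            mu = expit(eta)
            w = mu * (1 - mu)
            resid = y_s - mu
            grad_b = seg_sum(Z_s * resid[:, None])          # (G, d)
            grad_u = grad_b @ L - u
            F = seg_sum(w[:, None, None] * ZZ)              # (G, d, d)
            H = L.T @ F @ L + eye                           # (G, d, d) via broadcasting
            step = np.linalg.solve(H, grad_u[:, :, None])[:, :, 0]
            if np.max(np.abs(grad_u)) < 1e-9:
                break
            # step-halving per group on the penalized objective
            t = np.ones(G)
            for _ in range(20):
                cand = u + t[:, None] * step
                obj_c, eta_c = penalized(cand)
                worse = obj_c < obj - 1e-12
                if not worse.any():
                    break
                t[worse] *= 0.5
            u = u + t[:, None] * step
            obj, eta = penalized(u)
        mu = expit(eta)
        w = mu * (1 - mu)
        F = seg_sum(w[:, None, None] * ZZ)
        H = L.T @ F @ L + np.eye(d)
        return u, obj, H

    def neg_loglik(params: np.ndarray) -> float:
        beta = params[:k]
        L = _theta_to_L(params[k:], d, structure)
        u, obj, H = inner(beta, L, state["u"])
        state["u"] = u
        sign, logdet = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            return 1e10
        ll = float(np.sum(obj) - 0.5 * np.sum(logdet))
        return -ll

    beta0 = _init_beta(y_s, X_s)
    n_th = _n_theta(d, structure)
    if structure == "full":
        theta0 = np.zeros(n_th)
        pos = 0
        diag_idx = []
        for i in range(d):
            pos += i
            diag_idx.append(pos)
            pos += 1
        theta0[diag_idx] = 0.5
    else:
        diag_idx = list(range(n_th))
        theta0 = np.full(n_th, 0.5)
    x0 = np.concatenate([beta0, theta0])

    bounds: list[tuple] = [(None, None)] * k
    for j in range(n_th):
        bounds.append((0.0, None) if j in diag_idx else (None, None))

    res = optimize.minimize(
        neg_loglik,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_outer, "ftol": 1e-11, "gtol": gtol},
    )
    params = res.x
    beta = params[:k]
    L = _theta_to_L(params[k:], d, structure)
    loglik = -neg_loglik(params)

    # observed information for beta at theta-hat (central second differences)
    h = 1e-4 * np.maximum(1.0, np.abs(beta))

    def f_beta(b):
        return -neg_loglik(np.concatenate([b, params[k:]]))

    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f_beta(beta + ei + ej)
            fpm = f_beta(beta + ei - ej)
            fmp = f_beta(beta - ei + ej)
            fmm = f_beta(beta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    info = -H
    try:
        cov_beta = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov_beta), 0, None))
    except np.linalg.LinAlgError:
        cov_beta = np.full((k, k), np.nan)
        se = np.full(k, np.nan)

    if np.max(np.abs(beta)) > 10:
        raise SeparationError(
            "fixed-effect estimate diverged (|beta| > 10): quasi-complete separation"
        )

    n_params = k + n_th
    modes = state["u"] @ L.T
    return GLMMResult(
        beta=beta,
        se=se,
        cov_beta=cov_beta,
        L=L,
        cov_re=L @ L.T,
        loglik=loglik,
        aic=2 * n_params - 2 * loglik,
        converged=bool(res.success),
        n_obs=n,
        n_groups=G,
        structure=structure,
        modes=modes,
        n_iter=int(res.nit),
    )
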