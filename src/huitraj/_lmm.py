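"""Weighted maximum-likelihood linear mixed model with participant random
effects.

Marginal model per participant i (n_i repeated observations):

    y_i ~ N(X_i beta, sigma^2 * K_i),   K_i = I + Z_i A Z_i'

where Z_i is the random-effects design (intercept, or intercept and
centred-age slope) and ``sigma^2 A`` is the random-effect covariance G.
The weighted log-likelihood multiplies each participant's marginal
contribution by a participant weight w_i (design weights, survey bootstrap
replicate weights, or inverse-probability-of-attrition weights):

    l(beta, sigma^2, A) = sum_i w_i * log N(y_i | X_i beta, sigma^2 K_i)

beta and sigma^2 are profiled out in closed form (weighted GLS and the
weighted residual quadratic form), leaving a 1- or 3-parameter optimisation
over the log-Cholesky factor of A, solved with L-BFGS-B.  Participants are
batched by group size so all linear algebra is vectorised over blocks of
at most n_i x n_i (n_i <= number of cycles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize


class ConvergenceError(RuntimeError):
    """Raised when the profiled likelihood optimisation fails."""


class _DegenerateResult:
    """Stand-in optimiser result for the near-zero-residual shortcut."""

    def __init__(self, theta0):
        self.x = theta0
        self.success = True
        self.message = "degenerate: near-zero residual variance"


class RankDeficientError(ValueError):
    """Raised when the fixed-effects design is rank deficient."""


@dataclass
class LMMFit:
    beta: np.ndarray
    cov_beta: np.ndarray            # model-based: sigma^2 (sum w X'K^-1X)^-1
    sigma2: float                   # residual variance
    re_cov: np.ndarray              # G = sigma^2 * A
    loglik: float
    aic: float
    n_obs: int
    n_groups: int
    theta: np.ndarray               # log-Cholesky parameters of A (warm starts)
    converged: bool
    message: str


def _chol_from_theta(theta: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    if q == 1:
        L[0, 0] = np.exp(theta[0])
    else:
        L[0, 0] = np.exp(theta[0])
        L[1, 0] = theta[1]
        L[1, 1] = np.exp(theta[2])
    return L


def _batch_groups(X, y, Z, group_idx, weights):
    """Group rows by participant, batch participants by group size.

    Each batch records ``which``: the positions of its participants in the
    sorted-unique-group order.
    """
    order = np.argsort(group_idx, kind="stable")
    Xo, yo, Zo, go = X[order], y[order], Z[order], group_idx[order]
    uniq, starts, counts = np.unique(go, return_index=True, return_counts=True)
    batches = []
    for n_i in np.unique(counts):
        sel = counts == n_i
        rows = (starts[sel][:, None] + np.arange(n_i)[None, :]).ravel()
        m = sel.sum()
        batches.append(
            dict(
                X=Xo[rows].reshape(m, n_i, -1),
                y=yo[rows].reshape(m, n_i),
                Z=Zo[rows].reshape(m, n_i, -1),
                w=weights[sel],
                which=np.flatnonzero(sel),
                n=int(n_i),
            )
        )
    return batches, weights, counts


def _profiled(batches, A, p):
    """Profiled quantities at a given A: returns (XtKX, XtKy, ytKy, wlogdet, Nw)."""
    XtKX = np.zeros((p, p))
    XtKy = np.zeros(p)
    ytKy = 0.0
    wlogdet = 0.0
    Nw = 0.0
    for b in batches:
        Z, X, y, w, n = b["Z"], b["X"], b["y"], b["w"], b["n"]
        K = np.eye(n)[None] + np.einsum("mnq,qr,msr->mns", Z, A, Z)
        C = np.linalg.cholesky(K)
        # K^-1 X and K^-1 y via two triangular solves (batched)
        sol_X = np.linalg.solve(K, X)
        sol_y = np.linalg.solve(K, y[..., None])[..., 0]
        logdet = 2.0 * np.sum(np.log(np.diagonal(C, axis1=1, axis2=2)), axis=1)
        XtKX += np.einsum("m,mnp,mnq->pq", w, X, sol_X)
        XtKy += np.einsum("m,mnp,mn->p", w, X, sol_y)
        ytKy += float(np.einsum("m,mn,mn->", w, y, sol_y))
        wlogdet += float(w @ logdet)
        Nw += float(w.sum() * n)
    return XtKX, XtKy, ytKy, wlogdet, Nw


def _negloglik(theta, batches, p, q):
    """Profiled negative log-likelihood per unit weight (scale-free for the
    optimiser)."""
    A_L = _chol_from_theta(theta, q)
    A = A_L @ A_L.T
    XtKX, XtKy, ytKy, wlogdet, Nw = _profiled(batches, A, p)
    try:
        beta = np.linalg.solve(XtKX, XtKy)
    except np.linalg.LinAlgError:
        return 1e12
    quad = ytKy - beta @ XtKy
    if quad <= 0:
        quad = 1e-300
    sigma2 = quad / Nw
    ll = -0.5 * (Nw * (np.log(2.0 * np.pi * sigma2) + 1.0) + wlogdet)
    return -ll / Nw


def per_group_gls_moments(X, y, age_z, group_idx, theta, *, slope=True):
    """Per-participant GLS moment matrices at fixed variance parameters.

    Returns ``(G, h)`` with ``G[g] = X_g' K_g^-1 X_g`` and
    ``h[g] = X_g' K_g^-1 y_g`` aligned with the sorted unique group codes,
    so a weighted GLS solve under any participant weights is
    ``solve(sum_g w_g G_g, sum_g w_g h_g)``.  Used for fast survey
    bootstrap replicate refits: fixed effects and variance components are
    asymptotically orthogonal in the linear mixed model, so replicates
    re-solve the fixed effects at the main-fit variance parameters.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    q = 2 if slope else 1
    Z = np.ones((n, q))
    if slope:
        Z[:, 1] = np.asarray(age_z, float)
    codes = np.unique(group_idx)
    batches, _, _ = _batch_groups(X, y, Z, np.asarray(group_idx),
                                  np.ones(len(codes)))
    A_L = _chol_from_theta(np.asarray(theta, float), q)
    A = A_L @ A_L.T
    G = np.empty((len(codes), p, p))
    h = np.empty((len(codes), p))
    for b in batches:
        Zb, Xb, yb, nb = b["Z"], b["X"], b["y"], b["n"]
        K = np.eye(nb)[None] + np.einsum("mnq,qr,msr->mns", Zb, A, Zb)
        sol_X = np.linalg.solve(K, Xb)
        sol_y = np.linalg.solve(K, yb[..., None])[..., 0]
        G[b["which"]] = np.einsum("mnp,mnq->mpq", Xb, sol_X)
        h[b["which"]] = np.einsum("mnp,mn->mp", Xb, sol_y)
    return G, h


def fit_lmm(X, y, age_z, group_idx, weights=None, *, slope=True,
            theta0=None, maxiter=200):
    """Fit the weighted mixed model.

    Parameters
    ----------
    X : (n, p) fixed-effects design (already on a well-conditioned scale).
    y : (n,) outcome.
    age_z : (n,) centred/scaled age used for the random slope.
    group_idx : (n,) integer participant codes.
    weights : (n_groups,) per-participant weights aligned with the sorted
        unique group codes; ``None`` means unweighted.
    slope : include a random age slope in addition to the random intercept.
    theta0 : warm-start log-Cholesky parameters.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify collinear columns by QR pivoting for the error message
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = np.flatnonzero(diag < 1e-8 * diag.max()).tolist()
        raise RankDeficientError(
            f"fixed-effects design is rank deficient (rank {rank} < {p}); "
            f"suspect column indices {bad}"
        )
    q = 2 if slope else 1
    Z = np.ones((n, q))
    if slope:
        Z[:, 1] = np.asarray(age_z, float)
    codes, counts = np.unique(group_idx, return_counts=True)
    n_groups = len(codes)
    if n_groups < 2:
        raise ValueError("need at least 2 participants")
    if weights is None:
        w = np.ones(n_groups)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n_groups,):
            raise ValueError("weights must align with the unique participants")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    batches, w, counts = _batch_groups(X, y, Z, np.asarray(group_idx), w)

    if theta0 is None:
        theta0 = np.full(1 if q == 1 else 3, -0.5)
        if q == 2:
            theta0[1] = 0.0
    theta0 = np.asarray(theta0, float)
    # Near-exact data (residual variance ~ 0): the profiled objective is
    # dominated by floating-point cancellation and beta is invariant to
    # the variance parameters, so skip the optimisation.
    A0_L = _chol_from_theta(theta0, q)
    XtKX0, XtKy0, ytKy0, _, Nw0 = _profiled(batches, A0_L @ A0_L.T, p)
    quad0 = ytKy0 - np.linalg.solve(XtKX0, XtKy0) @ XtKy0
    if quad0 / Nw0 < 1e-12:
        res = _DegenerateResult(theta0)
    else:
        res = minimize(
            _negloglik, theta0, args=(batches, p, q),
            method="L-BFGS-B",
            bounds=[(-8.0, 8.0)] * len(np.atleast_1d(theta0)),
            options={"maxiter": maxiter, "ftol": 1e-11},
        )
        if not res.success and res.status != 1:  # status 1 = maxiter
            f0 = _negloglik(theta0, batches, p, q)
            if not (np.isfinite(res.fun) and res.fun <= f0 + 1e-6):
                raise ConvergenceError(
                    f"mixed-model optimisation failed: {res.message} "
                    f"(nit={res.nit}, fun={res.fun:.6g})"
                )
    theta = res.x
    A_L = _chol_from_theta(theta, q)
    A = A_L @ A_L.T
    XtKX, XtKy, ytKy, wlogdet, Nw = _profiled(batches, A, p)
    beta = np.linalg.solve(XtKX, XtKy)
    quad = ytKy - beta @ XtKy
    sigma2 = max(quad / Nw, 1e-300)
    loglik = -0.5 * (Nw * (np.log(2.0 * np.pi * sigma2) + 1.0) + wlogdet)
    cov_beta = sigma2 * np.linalg.inv(XtKX)
    n_var = len(theta) + 1  # variance components + residual
    aic = -2.0 * loglik + 2.0 * (p + n_var)
    return LMMFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma2=float(sigma2),
        re_cov=sigma2 * A,
        loglik=float(loglik),
        aic=float(aic),
        n_obs=n,
        n_groups=n_groups,
        theta=theta,
        converged=bool(res.success),
        message=str(res.message),
    )
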