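"""Linear mixed model machinery shared by the G×E and GWAS stages.

Two fitting routines are provided:

* :func:`reml_crossed` — REML for models with one or more independent
  random terms (identity covariance per term) and homogeneous residual,
  profiled so only the variance ratios are optimized. The Woodbury
  identity keeps each likelihood evaluation at one Cholesky of a
  q × q matrix (q = total number of random levels).
* :func:`fit_heteroscedastic_gls` — REML for a fixed-effects model with
  a separate residual variance per group (used for per-environment
  residuals when only one record per cell is available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize


def indicator(labels) -> tuple[np.ndarray, np.ndarray]:
    """Dense 0/1 design matrix for a factor; returns (Z, level order)."""
    labels = np.asarray(labels)
    levels, inv = np.unique(labels, return_inverse=True)
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), inv] = 1.0
    return Z, levels


@dataclass
class MixedFit:
    beta: np.ndarray
    sigma2: dict            # per-term variance, key = term name
    sigma2_e: float
    blups: dict             # per-term BLUP vector
    levels: dict            # per-term level labels
    pev: dict               # per-term PEV matrix (prediction error variance)
    loglik: float           # REML log-likelihood (up to a constant)
    converged: bool

    @property
    def variance_components(self) -> dict:
        out = dict(self.sigma2)
        out["residual"] = self.sigma2_e
        return out


def reml_crossed(
    y: np.ndarray,
    X: np.ndarray,
    terms: dict,
    tol_boundary: float = 1e-6,
    compute_pev: bool = False,
) -> MixedFit:
    """Fit y = Xβ + Σ_k Z_k u_k + e by REML, u_k ~ N(0, σ²_k I).

    Parameters
    ----------
    y, X
        Response and fixed-effect design (full column rank assumed after
        internal pruning).
    terms
        Mapping name → factor labels (length n); each becomes an
        independent random term with its own variance.
    tol_boundary
        Variance ratios below this (relative to σ²_e) are reported as 0.
    compute_pev
        If True, return the full PEV matrix per term (q_k × q_k).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(y)
    # prune collinear fixed-effect columns
    q_, r_, piv = linalg.qr(X, mode="economic", pivoting=True)
    rank = int(np.sum(np.abs(np.diag(r_)) > 1e-8 * np.abs(r_[0, 0])))
    keep_cols = np.sort(piv[:rank])
    Xr = X[:, keep_cols]
    p = Xr.shape[1]

    Zs, level_map = {}, {}
    for name, labels in terms.items():
        Z, lv = indicator(labels)
        Zs[name] = Z
        level_map[name] = lv
    names = list(Zs)
    sizes = [Zs[k].shape[1] for k in names]
    Z = np.concatenate([Zs[k] for k in names], axis=1)
    q = Z.shape[1]

    ZtZ = Z.T @ Z
    ZtX = Z.T @ Xr
    Zty = Z.T @ y
    XtX = Xr.T @ Xr
    Xty = Xr.T @ y
    yty = float(y @ y)

    col_term = np.concatenate(
        [np.full(s, i) for i, s in enumerate(sizes)]
    )

    def _assemble(log_gammas):
        g = np.exp(np.clip(log_gammas, -30.0, 30.0))
        s = np.sqrt(g[col_term])
        M = (s[:, None] * ZtZ) * s[None, :]
        M[np.diag_indices(q)] += 1.0
        cM, low = linalg.cho_factor(M, lower=True, check_finite=False)
        logdetM = 2.0 * np.sum(np.log(np.diag(cM)))
        SZtX = s[:, None] * ZtX
        SZty = s * Zty
        MinvSZtX = linalg.cho_solve((cM, low), SZtX, check_finite=False)
        MinvSZty = linalg.cho_solve((cM, low), SZty, check_finite=False)
        XtVX = XtX - SZtX.T @ MinvSZtX
        XtVy = Xty - SZtX.T @ MinvSZty
        ytVy = yty - SZty @ MinvSZty
        return g, s, (cM, low), logdetM, XtVX, XtVy, ytVy

    def neg2_reml(log_gammas):
        try:
            _, _, _, logdetM, XtVX, XtVy, ytVy = _assemble(log_gammas)
            cX = linalg.cho_factor(XtVX, check_finite=False)
        except linalg.LinAlgError:
            return 1e30
        beta = linalg.cho_solve(cX, XtVy, check_finite=False)
        ypy = max(ytVy - XtVy @ beta, 1e-300)
        sigma2e = ypy / (n - p)
        logdetXtVX = 2.0 * np.sum(np.log(np.diag(cX[0])))
        return (n - p) * np.log(sigma2e) + logdetM + logdetXtVX

    x0 = np.zeros(len(names))
    res = optimize.minimize(
        neg2_reml, x0, method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-7, "maxiter": 1000},
    )

    g, s, cMlow, logdetM, XtVX, XtVy, ytVy = _assemble(res.x)
    cX = linalg.cho_factor(XtVX, check_finite=False)
    beta_r = linalg.cho_solve(cX, XtVy, check_finite=False)
    ypy = ytVy - XtVy @ beta_r
    # noiseless data can push the residual quadratic form to roundoff level
    floor = 1e-12 * float(np.var(y)) + 1e-300
    sigma2e = float(max(ypy / (n - p), floor))

    # BLUPs: u_k = γ_k Z_k' Vtilde^{-1} (y − Xβ)
    resid_t = Zty - ZtX @ beta_r
    # Z' Vt^{-1} r = Z'r − Z'Za M^{-1} Za'r ; Za = Z diag(s)
    ZtZa = ZtZ * s[None, :]
    ZaT_r = s * resid_t
    ZtVinv_r = resid_t - ZtZa @ linalg.cho_solve(cMlow, ZaT_r, check_finite=False)
    u_all = g[col_term] * ZtVinv_r

    blups, sigma2, pevs = {}, {}, {}
    off = 0
    for name, size in zip(names, sizes):
        sl = slice(off, off + size)
        blups[name] = u_all[sl]
        gamma = g[names.index(name)]
        sigma2[name] = 0.0 if gamma < tol_boundary else float(gamma * sigma2e)
        off += size

    if compute_pev:
        # T = Z' Vt^{-1} Z ; A = Z' Vt^{-1} X ; Z'PZ = T − A (X'Vt^{-1}X)^{-1} A'
        MinvSZtZ = linalg.cho_solve(cMlow, (s[:, None] * ZtZ), check_finite=False)
        T = ZtZ - (ZtZ * s[None, :]) @ MinvSZtZ
        A = ZtX - (ZtZ * s[None, :]) @ linalg.cho_solve(
            cMlow, s[:, None] * ZtX, check_finite=False
        )
        ZPZ = T - A @ linalg.cho_solve(cX, A.T, check_finite=False)
        off = 0
        for i, (name, size) in enumerate(zip(names, sizes)):
            sl = slice(off, off + size)
            gam = g[i]
            block = ZPZ[sl, sl]
            pev = sigma2e * (gam * np.eye(size) - gam * block * gam)
            pevs[name] = pev
            off += size

    beta = np.zeros(X.shape[1])
    beta[keep_cols] = beta_r
    return MixedFit(
        beta=beta,
        sigma2=sigma2,
        sigma2_e=sigma2e,
        blups=blups,
        levels=level_map,
        pev=pevs,
        loglik=-0.5 * float(res.fun),
        converged=bool(res.success or res.fun < 1e29),
    )


@dataclass
class HetGlsFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_by_group: np.ndarray
    group_levels: np.ndarray
    loglik: float


def fit_heteroscedastic_gls(
    y: np.ndarray, X: np.ndarray, groups, max_iter: int = 200
) -> HetGlsFit:
    """REML fit of y = Xβ + e with Var(e_i) = σ²_{g(i)} per group.

    Optimizes the REML log-likelihood over the per-group log variances
    with analytic profiling of β.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    groups = np.asarray(groups)
    levels, ginv = np.unique(groups, return_inverse=True)
    G = len(levels)
    n, p = X.shape

    def neg2_reml(log_s2):
        s2 = np.exp(np.clip(log_s2, -30, 30))
        w = 1.0 / s2[ginv]
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        XtWy = Xw.T @ y
        try:
            c = linalg.cho_factor(XtWX, check_finite=False)
        except linalg.LinAlgError:
            return 1e30
        beta = linalg.cho_solve(c, XtWy, check_finite=False)
        r = y - X @ beta
        quad = float(np.sum(w * r * r))
        logdetV = float(np.sum(np.log(s2[ginv])))
        logdetXtWX = 2.0 * np.sum(np.log(np.diag(c[0])))
        return logdetV + logdetXtWX + quad

    # start from pooled OLS residual variance
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    r0 = y - X @ beta0
    start = np.log(np.maximum(
        np.array([np.mean(r0[ginv == g] ** 2) for g in range(G)]), 1e-8
    ))
    res = optimize.minimize(
        neg2_reml, start, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000},
    )
    s2 = np.exp(res.x)
    w = 1.0 / s2[ginv]
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    c = linalg.cho_factor(XtWX, check_finite=False)
    beta = linalg.cho_solve(c, Xw.T @ y, check_finite=False)
    cov = linalg.cho_solve(c, np.eye(p), check_finite=False)
    return HetGlsFit(
        beta=beta,
        cov_beta=cov,
        sigma2_by_group=s2,
        group_levels=levels,
        loglik=-0.5 * float(res.fun),
    )


def cullis_h2(pev: np.ndarray, sigma2_g: float) -> float:
    """Generalized heritability 1 − v̄Δ / (2 σ²_g).

    v̄Δ is the mean prediction-error variance of all pairwise BLUP
    differences, computed from the full PEV matrix.
    """
    if sigma2_g <= 0:
        return 0.0
    q = pev.shape[0]
    if q < 2:
        return float("nan")
    d = np.diag(pev)
    # mean over i<j of (pev_ii + pev_jj − 2 pev_ij)
    sum_d = d.sum()
    vbar = (2.0 * q * sum_d - 2.0 * sum_d - 2.0 * (pev.sum() - sum_d)) / (
        q * (q - 1)
    )
    return float(max(0.0, min(1.0, 1.0 - vbar / (2.0 * sigma2_g))))
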