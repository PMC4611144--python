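"""Vectorized maximum-likelihood fitting of the random-intercept/slope LMM.

Per voxel v, the longitudinal model is

    y_ij = beta0 + beta1 t_ij + b_i0 + b_i1 t_ij + eps_ij,
    (b_i0, b_i1)' ~ N(0, G),   eps_ij ~ N(0, sigma_eps^2),

fitted by maximum likelihood with an EM algorithm run simultaneously for
all voxels: the per-voxel quantities are leading array axes, so one EM
iteration is a handful of batched small-matrix operations.  Subjects are
grouped by identical visit-time vectors, which makes the marginal
covariance shared within a group.

EM keeps G positive semidefinite and sigma_eps^2 positive by construction
and increases the likelihood monotonically.  Inference on the fixed slope
is Wald: t1 = beta1 / SE(beta1) with SE from the inverse GLS information
at the final variance estimates, referred to the standard normal.

Fallback chain per voxel: full model -> random intercept only -> pooled
OLS with a cluster-robust (by subject) sandwich variance; the ``model``
code records which estimator produced the reported numbers (2, 1, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["LmmResult", "fit_random_slope_lmm"]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class LmmResult:
    """Per-voxel estimates from :func:`fit_random_slope_lmm` (flat arrays)."""

    beta0: np.ndarray
    beta1: np.ndarray
    se1: np.ndarray
    t1: np.ndarray
    p1: np.ndarray
    sigma2_0: np.ndarray
    sigma2_1: np.ndarray
    sigma_01: np.ndarray
    sigma2_eps: np.ndarray
    loglik: np.ndarray
    converged: np.ndarray
    degenerate: np.ndarray
    model: np.ndarray       # 2 full, 1 intercept-only, 0 OLS fallback
    n_iter: np.ndarray


def _group_by_times(subject_id, time):
    """Group subject column-blocks by identical visit-time vectors."""
    subject_id = np.asarray(subject_id)
    time = np.asarray(time, dtype=float)
    blocks = []
    start = 0
    for j in range(1, len(subject_id) + 1):
        if j == len(subject_id) or subject_id[j] != subject_id[start]:
            blocks.append((start, j))
            start = j
    groups: dict[tuple, list] = {}
    for start, stop in blocks:
        key = tuple(np.round(time[start:stop], 12))
        groups.setdefault(key, []).append((start, stop))
    out = []
    for key, blks in groups.items():
        cols = np.concatenate([np.arange(a, b) for a, b in blks])
        out.append((np.array(key, dtype=float), cols, len(blks)))
    return out


def _em_fit(Y, groups_data, *, q, max_iter, tol):
    """EM for ML; ``q`` random-effect columns of X = [1, t] (q = 2 or 1)."""
    nvox = Y.shape[0]
    Gx = groups_data
    Jtot = sum(g["J"] * g["n"] for g in Gx)
    Nsubj = sum(g["n"] for g in Gx)

    # init from pooled OLS
    Xall = np.concatenate([np.tile(g["X"], (g["n"], 1)) for g in Gx])
    yall = np.concatenate([g["Y"].reshape(nvox, -1) for g in Gx], axis=1)
    coef, *_ = np.linalg.lstsq(Xall, yall.T, rcond=None)
    beta = coef.T
    resid = yall - beta @ Xall.T
    s2 = np.maximum(resid.var(axis=1), 1e-12)
    # keep sigma^2 bounded away from zero relative to the data scale so a
    # residual-free voxel (deterministic response) stays numerically sane
    s2_floor = 1e-10 * np.maximum(yall.var(axis=1), 1e-12)
    var_t = Xall[:, 1].var() + 1e-12
    G = np.zeros((nvox, q, q))
    G[:, 0, 0] = 0.25 * s2
    if q == 2:
        G[:, 1, 1] = 0.25 * s2 / var_t
    sigma2 = 0.5 * s2

    active = np.arange(nvox)
    ll_prev = np.full(nvox, -np.inf)
    converged = np.zeros(nvox, dtype=bool)
    n_iter = np.zeros(nvox, dtype=int)

    for it in range(max_iter):
        a = active
        if a.size == 0:
            break
        Ga, s2a = G[a], sigma2[a]

        A = np.zeros((a.size, 2, 2))
        rhs = np.zeros((a.size, 2))
        Ws, logdets = [], []
        for g in Gx:
            X, Z, Jg, ns = g["X"], g["X"][:, :q], g["J"], g["n"]
            ZG = np.einsum("jk,nkl->njl", Z, Ga)
            V = np.einsum("njl,ml->njm", ZG, Z) + s2a[:, None, None] * np.eye(Jg)
            W = np.linalg.inv(V)
            _, ld = np.linalg.slogdet(V)
            Ws.append(W)
            logdets.append(ld)
            XtW = np.einsum("ja,njk->nak", X, W)
            A += ns * np.einsum("nak,kb->nab", XtW, X)
            rhs += np.einsum("nak,nk->na", XtW, g["Y"][a].sum(axis=1))
        beta_a = np.linalg.solve(A, rhs[..., None])[..., 0]

        Sb = np.zeros((a.size, q, q))
        sse = np.zeros(a.size)
        quad = np.zeros(a.size)
        for g, W, ld in zip(Gx, Ws, logdets):
            X, Z, ns = g["X"], g["X"][:, :q], g["n"]
            pred = beta_a @ X.T
            R = g["Y"][a] - pred[:, None, :]
            quad += np.einsum("nij,njk,nik->n", R, W, R)
            M = np.einsum("nkl,jl,njm->nkm", Ga, Z, W)       # G Z' V^-1
            bhat = np.einsum("nkm,nim->nik", M, R)
            Cpost = Ga - np.einsum("nkj,jl,nlm->nkm", M, Z, Ga)
            Sb += np.einsum("nik,nil->nkl", bhat, bhat) + ns * Cpost
            E = R - np.einsum("jk,nik->nij", Z, bhat)
            sse += (E ** 2).sum(axis=(1, 2))
            sse += ns * np.einsum("jk,nkl,jl->n", Z, Cpost, Z)

        ll_a = -0.5 * (np.array([g["n"] for g in Gx]) @ np.array(logdets)
                       + quad + Jtot * _LOG2PI)
        G[a] = 0.5 * (Sb + np.swapaxes(Sb, 1, 2)) / Nsubj
        sigma2[a] = np.maximum(sse / Jtot, s2_floor[a])
        n_iter[a] = it + 1

        done = np.abs(ll_a - ll_prev[a]) < tol * (np.abs(ll_a) + 1.0)
        converged[a[done]] = True
        ll_prev[a] = ll_a
        active = a[~done]

    # final GLS beta, information and loglik at the last variance estimates
    A = np.zeros((nvox, 2, 2))
    rhs = np.zeros((nvox, 2))
    quad = np.zeros(nvox)
    logdet_tot = np.zeros(nvox)
    Vs = []
    for g in Gx:
        X, Z, Jg, ns = g["X"], g["X"][:, :q], g["J"], g["n"]
        ZG = np.einsum("jk,nkl->njl", Z, G)
        V = np.einsum("njl,ml->njm", ZG, Z) + sigma2[:, None, None] * np.eye(Jg)
        W = np.linalg.inv(V)
        Vs.append(W)
        _, ld = np.linalg.slogdet(V)
        logdet_tot += ns * ld
        XtW = np.einsum("ja,njk->nak", X, W)
        A += ns * np.einsum("nak,kb->nab", XtW, X)
        rhs += np.einsum("nak,nk->na", XtW, g["Y"].sum(axis=1))
    beta = np.linalg.solve(A, rhs[..., None])[..., 0]
    for g, W in zip(Gx, Vs):
        pred = beta @ g["X"].T
        R = g["Y"] - pred[:, None, :]
        quad += np.einsum("nij,njk,nik->n", R, W, R)
    loglik = -0.5 * (logdet_tot + quad + Jtot * _LOG2PI)
    cov_beta = np.linalg.inv(A)
    se1 = np.sqrt(np.maximum(cov_beta[:, 1, 1], 0.0))

    Gfull = np.zeros((nvox, 2, 2))
    Gfull[:, :q, :q] = G
    return {
        "beta": beta, "se1": se1, "G": Gfull, "sigma2": sigma2,
        "loglik": loglik, "converged": converged, "n_iter": n_iter,
    }


def _ols_sandwich(Y, Gx):
    """Pooled OLS with cluster-robust (by subject) slope variance."""
    nvox = Y.shape[0]
    Xall = np.concatenate([np.tile(g["X"], (g["n"], 1)) for g in Gx])
    yall = np.concatenate([g["Y"].reshape(nvox, -1) for g in Gx], axis=1)
    XtX_inv = np.linalg.inv(Xall.T @ Xall)
    beta = yall @ Xall @ XtX_inv.T
    meat = np.zeros((nvox, 2, 2))
    for g in Gx:
        X = g["X"]
        R = g["Y"] - (beta @ X.T)[:, None, :]
        S = np.einsum("nij,jk->nik", R, X)      # per-subject score
        meat += np.einsum("nik,nil->nkl", S, S)
    cov = XtX_inv @ meat @ XtX_inv
    se1 = np.sqrt(np.maximum(cov[:, 1, 1], 0.0))
    return beta, se1


def fit_random_slope_lmm(
    data: np.ndarray,
    subject_id,
    time,
    *,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> LmmResult:
    """Fit the random-intercept/slope model at every row of ``data``.

    ``data`` is (n_voxels, J) with columns ordered like the image stack.
    Voxels with zero response variance are flagged ``degenerate`` and get
    t1 = 0, p1 = 1.
    """
    Y = np.asarray(data, dtype=float)
    nvox, J = Y.shape
    groups = _group_by_times(subject_id, time)

    degenerate = Y.var(axis=1) <= 0.0
    idx_fit = np.flatnonzero(~degenerate)

    out = {k: np.zeros(nvox) for k in
           ["beta0", "beta1", "t1", "sigma2_0", "sigma2_1", "sigma_01"]}
    se1 = np.full(nvox, np.nan)
    s2e = np.full(nvox, np.nan)
    ll = np.full(nvox, np.nan)
    p1 = np.ones(nvox)
    conv = np.zeros(nvox, dtype=bool)
    model = np.full(nvox, -1, dtype=int)
    model[degenerate] = -1
    niter = np.zeros(nvox, dtype=int)

    if idx_fit.size:
        Gx = [{"t": t, "X": np.column_stack([np.ones_like(t), t]),
               "Y": Y[idx_fit][:, cols].reshape(idx_fit.size, n, t.size),
               "n": n, "J": t.size} for t, cols, n in groups]
        res = _em_fit(Y[idx_fit], Gx, q=2, max_iter=max_iter, tol=tol)
        beta, s1, G, s2, lg, cg, ni = (res["beta"], res["se1"], res["G"],
                                       res["sigma2"], res["loglik"],
                                       res["converged"], res["n_iter"])
        mdl = np.full(idx_fit.size, 2, dtype=int)

        bad = ~(np.isfinite(beta).all(axis=1) & np.isfinite(s1) & (s1 > 0))
        if bad.any():
            Gx_b = [dict(g, Y=g["Y"][bad]) for g in Gx]
            res1 = _em_fit(Y[idx_fit][bad], Gx_b, q=1,
                           max_iter=max_iter, tol=tol)
            for arr, new in [(beta, res1["beta"]), (s1, res1["se1"]),
                             (G, res1["G"]), (s2, res1["sigma2"]),
                             (lg, res1["loglik"]), (cg, res1["converged"]),
                             (ni, res1["n_iter"])]:
                arr[bad] = new
            mdl[bad] = 1
            still = bad.copy()
            still[bad] = ~(np.isfinite(res1["beta"]).all(axis=1)
                           & np.isfinite(res1["se1"]) & (res1["se1"] > 0))
            if still.any():
                Gx_s = [dict(g, Y=g["Y"][still]) for g in Gx]
                b_o, s_o = _ols_sandwich(Y[idx_fit][still], Gx_s)
                beta[still], s1[still] = b_o, s_o
                cg[still] = False
                mdl[still] = 0

        out["beta0"][idx_fit] = beta[:, 0]
        out["beta1"][idx_fit] = beta[:, 1]
        se1[idx_fit] = s1
        out["sigma2_0"][idx_fit] = G[:, 0, 0]
        out["sigma2_1"][idx_fit] = G[:, 1, 1]
        out["sigma_01"][idx_fit] = G[:, 0, 1]
        s2e[idx_fit] = s2
        ll[idx_fit] = lg
        conv[idx_fit] = cg
        model[idx_fit] = mdl
        niter[idx_fit] = ni

    ok = ~degenerate & np.isfinite(se1) & (se1 > 0)
    out["t1"][ok] = out["beta1"][ok] / se1[ok]
    p1[ok] = 2.0 * stats.norm.sf(np.abs(out["t1"][ok]))

    return LmmResult(
        beta0=out["beta0"], beta1=out["beta1"], se1=se1, t1=out["t1"], p1=p1,
        sigma2_0=out["sigma2_0"], sigma2_1=out["sigma2_1"],
        sigma_01=out["sigma_01"], sigma2_eps=s2e, loglik=ll,
        converged=conv, degenerate=degenerate, model=model, n_iter=niter,
    )
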