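"""Longitudinal functional PCA for high-dimensional image stacks.

The model: each demeaned image is

    y~_ij = Phi_X0 xi_i + t_ij Phi_X1 xi_i + Phi_W zeta_ij,

a subject-specific process with a baseline part (random imaging intercept,
``Phi_X0``) and a longitudinal part (random imaging slope, ``Phi_X1``)
sharing the scores ``xi_i``, plus a visit-specific deviation ``Phi_W``
with scores ``zeta_ij``.  Components are eigenvectors of the covariance
operators of the two latent processes, estimated by a method of moments:
the expected outer product of two within-subject images is a linear
function of their visit times,

    E[y~_ij1 y~_ij2'] = K00 + t_ij2 K01 + t_ij1 K10
                        + t_ij1 t_ij2 K11 + delta_j1j2 KW,

so the covariance blocks are recovered by ordinary least squares on the
design vectors f = (1, t_ij2, t_ij1, t_ij1*t_ij2, delta)'.

Everything is computed in the J-dimensional reduced space obtained from a
thin SVD of the demeaned data matrix, y~ = V S U'.  Multiplying the model
by V' preserves the correlation structure, so the eigendecomposition and
the BLUP scores computed on the reduced images w_j = S U'_j coincide with
their full-space counterparts, while memory scales with J rather than the
number of voxels.  Full-space eigenimages are recovered as Phi = V A.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, SingularDesignError
from .stack import ImageStack

__all__ = [
    "ReducedData",
    "MomentDesign",
    "CovBlocks",
    "LfpcaFit",
    "demean",
    "reduce_stack",
    "build_moment_design",
    "estimate_cov_blocks",
    "eigendecompose",
    "variance_table",
    "estimate_scores",
    "backproject",
    "component_trajectory",
    "fit_lfpca",
    "save_fit",
    "load_fit",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class ReducedData:
    """Thin-SVD factors of the demeaned data matrix, y~ = V S U'.

    ``V`` has orthonormal columns (p x r), ``S`` the singular values
    (descending), ``U`` (J x r).  Column j of ``W_red = S U'`` is the
    r-dimensional reduced representation of demeaned image j.
    """

    V: np.ndarray
    S: np.ndarray
    U: np.ndarray
    mean_map: np.ndarray | None = None

    @property
    def rank(self) -> int:
        return self.S.size

    @property
    def W_red(self) -> np.ndarray:
        return self.S[:, None] * self.U.T


@dataclass
class MomentDesign:
    """Design for the method-of-moments OLS over within-subject visit pairs.

    ``F`` is 5 x m with one column per ordered pair (j1, j2) of visits of
    the same subject (including j1 = j2); m = sum_i J_i^2.
    """

    F: np.ndarray
    subject: np.ndarray   # (m,) subject id per pair
    j1: np.ndarray        # (m,) within-subject visit positions (0-based)
    j2: np.ndarray

    @property
    def m(self) -> int:
        return self.F.shape[1]


@dataclass
class CovBlocks:
    """Reduced-space covariance blocks: subject process (K00..K11) and KW."""

    K00: np.ndarray
    K01: np.ndarray
    K10: np.ndarray
    K11: np.ndarray
    KW: np.ndarray

    @property
    def stacked(self) -> np.ndarray:
        """The symmetric 2r x 2r stacked subject-process covariance."""
        return np.block([[self.K00, self.K01], [self.K10, self.K11]])


@dataclass
class LfpcaFit:
    """Estimated LFPCA decomposition.

    ``A_x0``/``A_x1`` are the reduced baseline/longitudinal halves of the
    subject-specific eigenvectors: the stacked vector (A_x0[:, k]; A_x1[:, k])
    has unit norm, so ``||A_x1[:, k]||^2`` is the longitudinal ratio of
    component k.  Full-space eigenimages are ``V @ A``.
    """

    lambda_x: np.ndarray
    A_x0: np.ndarray
    A_x1: np.ndarray
    lambda_w: np.ndarray
    A_w: np.ndarray
    reduced: ReducedData
    subject_id: np.ndarray
    visit_index: np.ndarray
    time: np.ndarray
    xi: np.ndarray | None = None
    zeta: np.ndarray | None = None
    mask: np.ndarray | None = None
    voxel_size: tuple | None = None
    time_offset: float = 0.0

    @property
    def n_x(self) -> int:
        return self.lambda_x.size

    @property
    def n_w(self) -> int:
        return self.lambda_w.size

    @property
    def var_total(self) -> float:
        return float(self.lambda_x.sum() + self.lambda_w.sum())

    @property
    def longitudinal_ratios(self) -> np.ndarray:
        """||A_x1_k||^2 per subject-specific component (a [0, 1] quantity)."""
        return (self.A_x1 ** 2).sum(axis=0)

    @property
    def subjects(self) -> np.ndarray:
        _, first = np.unique(self.subject_id, return_index=True)
        return self.subject_id[np.sort(first)]

    def subject_blocks(self):
        sid = self.subject_id
        start = 0
        for j in range(1, len(sid) + 1):
            if j == len(sid) or sid[j] != sid[start]:
                yield sid[start], slice(start, j)
                start = j


# ---------------------------------------------------------------------------
# estimation steps

def demean(stack: ImageStack):
    """Subtract the voxelwise sample mean over all images.

    Returns ``(mean_map, demeaned_stack)``.  The sample mean over all image
    observations is the mean-surface estimate used throughout; no
    time-varying mean is fitted.
    """
    mean_map = stack.data.mean(axis=1)
    return mean_map, stack.with_data(stack.data - mean_map[:, None])


def reduce_stack(stack: ImageStack, mean_map: np.ndarray | None = None) -> ReducedData:
    """Thin SVD of the demeaned data matrix.

    Rank is the number of singular values above the machine-scaled
    tolerance ``max(p, J) * eps * s_max``.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    V, S, Ut = np.linalg.svd(data, full_matrices=False)
    if S.size == 0 or S[0] == 0.0:
        raise DegenerateDataError("data matrix is identically zero")
    tol = max(data.shape) * np.finfo(float).eps * S[0]
    r = int(np.sum(S > tol))
    return ReducedData(V=V[:, :r], S=S[:r], U=Ut[:r].T, mean_map=mean_map)


def build_moment_design(subject_id, time) -> MomentDesign:
    """All ordered within-subject visit pairs with design vectors f.

    f_(i,j1,j2) = (1, t_ij2, t_ij1, t_ij1 * t_ij2, delta_j1j2)'.
    """
    subject_id = np.asarray(subject_id)
    time = np.asarray(time, dtype=float)
    cols, subs, a_idx, b_idx = [], [], [], []
    start = 0
    for j in range(1, len(subject_id) + 1):
        if j == len(subject_id) or subject_id[j] != subject_id[start]:
            t = time[start:j]
            for j1 in range(len(t)):
                for j2 in range(len(t)):
                    cols.append((1.0, t[j2], t[j1], t[j1] * t[j2],
                                 1.0 if j1 == j2 else 0.0))
                    subs.append(subject_id[start])
                    a_idx.append(start + j1)
                    b_idx.append(start + j2)
            start = j
    F = np.array(cols, dtype=float).T
    if np.linalg.matrix_rank(F) < 5:
        raise SingularDesignError(
            "moment design F*F' is singular; the visit times carry too "
            "little variation (each subject needs >= 3 visits or "
            "sufficiently varied times)"
        )
    return MomentDesign(F=F, subject=np.asarray(subs),
                        j1=np.asarray(a_idx), j2=np.asarray(b_idx))


def estimate_cov_blocks(
    reduced: ReducedData,
    design: MomentDesign,
    *,
    cond_bound: float = 1e10,
) -> CovBlocks:
    """Method-of-moments OLS estimate of the reduced covariance blocks.

    Regresses the pair outer products w_j1 w_j2' on the 5-vector f and
    reshapes the coefficient columns into r x r blocks.  The response is
    accumulated pair-block by pair-block; no p^2- or r^2-by-m matrix is
    ever materialized.  Blocks are symmetrized on exit.
    """
    F = design.F
    FFt = F @ F.T
    cond = np.linalg.cond(FFt)
    if not np.isfinite(cond) or cond > cond_bound:
        raise SingularDesignError(
            f"moment design is ill-conditioned: cond(F F') = {cond:.3g} "
            f"exceeds the bound {cond_bound:.3g}"
        )
    # G[pair, q]: OLS weight of pair outer-product on coefficient block q
    G = np.linalg.solve(FFt, F).T
    W = reduced.W_red
    r = W.shape[0]
    K = np.zeros((5, r, r))
    # blocked accumulation: for each subject, K_q += W_i C_q W_i'
    pos = 0
    m = design.m
    while pos < m:
        sid = design.subject[pos]
        end = pos
        while end < m and design.subject[end] == sid:
            end += 1
        ji = int(round(np.sqrt(end - pos)))
        Wi = W[:, design.j1[pos]:design.j1[pos] + ji]
        C = G[pos:end].reshape(ji, ji, 5)
        for q in range(5):
            K[q] += Wi @ C[:, :, q] @ Wi.T
        pos = end
    K00, K01, K10, K11, KW = K
    K00 = 0.5 * (K00 + K00.T)
    K11 = 0.5 * (K11 + K11.T)
    KW = 0.5 * (KW + KW.T)
    K01 = 0.5 * (K01 + K10.T)
    return CovBlocks(K00=K00, K01=K01, K10=K01.T, K11=K11, KW=KW)


def _truncate(vals: np.ndarray, n, max_components: int | None, what: str) -> int:
    """Number of leading positive eigenvalues to keep."""
    npos = vals.size
    if npos == 0:
        if n:
            warnings.warn(f"no positive {what} eigenvalue; keeping 0 components")
        return 0
    if isinstance(n, (bool,)):
        raise TypeError("truncation setting must be an int count or float fraction")
    if isinstance(n, (int, np.integer)):
        k = min(int(n), npos)
    else:
        frac = float(n)
        if not 0 < frac <= 1:
            raise ValueError(f"variance fraction must be in (0, 1], got {frac}")
        cum = np.cumsum(vals) / vals.sum()
        k = int(np.searchsorted(cum, frac - 1e-12) + 1)
    if max_components is not None:
        k = min(k, int(max_components))
    return k


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive."""
    if vecs.size == 0:
        return vecs
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def eigendecompose(
    blocks: CovBlocks,
    reduced: ReducedData,
    subject_id,
    visit_index,
    time,
    *,
    n_x=0.9,
    n_w=0.9,
    max_components: int | None = 10,
    mask=None,
    voxel_size=None,
) -> LfpcaFit:
    """Eigendecompose the stacked subject covariance and KW; truncate.

    ``n_x``/``n_w``: an integer keeps that many components, a float in
    (0, 1] keeps the smallest number of components reaching that fraction
    of the summed **positive** eigenvalue mass.  Non-positive eigenvalues
    (possible under the method of moments) are discarded outright, never
    clipped into the retained set.  ``max_components`` caps both counts.
    """
    r = blocks.KW.shape[0]
    vals_x, vecs_x = np.linalg.eigh(blocks.stacked)
    order = np.argsort(vals_x)[::-1]
    vals_x, vecs_x = vals_x[order], vecs_x[:, order]
    pos = vals_x > 0
    vals_x, vecs_x = vals_x[pos], vecs_x[:, pos]
    kx = _truncate(vals_x, n_x, max_components, "subject-specific")
    vecs_x = _fix_signs(vecs_x[:, :kx])
    vals_x = vals_x[:kx]

    vals_w, vecs_w = np.linalg.eigh(blocks.KW)
    order = np.argsort(vals_w)[::-1]
    vals_w, vecs_w = vals_w[order], vecs_w[:, order]
    pos = vals_w > 0
    vals_w, vecs_w = vals_w[pos], vecs_w[:, pos]
    kw = _truncate(vals_w, n_w, max_components, "visit-specific")
    vecs_w = _fix_signs(vecs_w[:, :kw])
    vals_w = vals_w[:kw]

    return LfpcaFit(
        lambda_x=vals_x,
        A_x0=vecs_x[:r, :],
        A_x1=vecs_x[r:, :],
        lambda_w=vals_w,
        A_w=vecs_w,
        reduced=reduced,
        subject_id=np.asarray(subject_id),
        visit_index=np.asarray(visit_index),
        time=np.asarray(time, dtype=float),
        mask=mask,
        voxel_size=voxel_size,
    )


def variance_table(fit: LfpcaFit) -> pd.DataFrame:
    """Variance attribution per retained component.

    Columns: ``process`` ("subject" or "visit"), 1-based ``component``,
    ``eigenvalue``, ``variance_share`` (of the total retained variance) and,
    for subject-specific components, the ``longitudinal_ratio``
    ||Phi_X1_k||^2 / (||Phi_X0_k||^2 + ||Phi_X1_k||^2) = ||A_x1_k||^2.
    """
    total = fit.var_total
    rows = []
    ratios = fit.longitudinal_ratios
    for k in range(fit.n_x):
        rows.append(("subject", k + 1, fit.lambda_x[k],
                     fit.lambda_x[k] / total, ratios[k]))
    for l in range(fit.n_w):
        rows.append(("visit", l + 1, fit.lambda_w[l],
                     fit.lambda_w[l] / total, np.nan))
    return pd.DataFrame(
        rows, columns=["process", "component", "eigenvalue",
                       "variance_share", "longitudinal_ratio"]
    )


def estimate_scores(fit: LfpcaFit) -> tuple[np.ndarray, np.ndarray]:
    """BLUP scores by per-subject least squares on the reduced images.

    For subject i the stacked reduced data vec(w_i) is regressed on the
    design with per-visit blocks [A_x0 + t_ij A_x1 | block-diagonal A_w]:
    omega_i = (B'B)^(-1) B' vec(w_i).  When B is rank deficient the
    minimum-norm solution is returned with a warning.  By linearity the
    result is identical to the full-space computation.

    Returns ``(xi, zeta)`` and stores them on ``fit``.
    """
    r = fit.reduced.rank
    W = fit.reduced.W_red
    nx, nw = fit.n_x, fit.n_w
    subjects = list(fit.subject_blocks())
    xi = np.zeros((len(subjects), nx))
    zeta = np.zeros((fit.time.size, nw))
    for i, (sid, sl) in enumerate(subjects):
        ji = sl.stop - sl.start
        t = fit.time[sl]
        ncol = nx + ji * nw
        if ncol > ji * r:
            warnings.warn(
                f"subject {sid!r}: {ncol} score parameters exceed {ji * r} "
                "observations; scores are rank deficient"
            )
        B = np.zeros((ji * r, ncol))
        for j in range(ji):
            B[j * r:(j + 1) * r, :nx] = fit.A_x0 + t[j] * fit.A_x1
            B[j * r:(j + 1) * r, nx + j * nw:nx + (j + 1) * nw] = fit.A_w
        y = W[:, sl].T.ravel()
        sol, _, rank, _ = np.linalg.lstsq(B, y, rcond=None)
        if rank < ncol:
            warnings.warn(
                f"subject {sid!r}: score design rank {rank} < {ncol}; "
                "returning the minimum-norm solution"
            )
        xi[i] = sol[:nx]
        zeta[sl] = sol[nx:].reshape(ji, nw)
    fit.xi, fit.zeta = xi, zeta
    return xi, zeta


def backproject(fit: LfpcaFit, which: str = "baseline", k=None) -> np.ndarray:
    """Full-space eigenimages Phi = V A for the requested components.

    ``which`` is one of ``"baseline"`` (Phi_X0), ``"longitudinal"``
    (Phi_X1) or ``"visit"`` (Phi_W); ``k`` selects a single component
    (0-based) or, if None, all retained ones.  Returns a p-vector or a
    p x N array.
    """
    A = {"baseline": fit.A_x0, "longitudinal": fit.A_x1,
         "visit": fit.A_w}.get(which)
    if A is None:
        raise ValueError(f"unknown component family {which!r}")
    if k is not None:
        n = A.shape[1]
        if not -n <= k < n:
            raise IndexError(f"component {k} out of range (have {n})")
        A = A[:, k]
    return fit.reduced.V @ A


def component_trajectory(fit: LfpcaFit, k: int, times) -> np.ndarray:
    """Maps Phi_X0_k + t * Phi_X1_k for each requested time.

    The longitudinal eigenimage is added to the baseline one with time as a
    multiplicative weight; returns an array of shape (len(times), p).
    """
    base = backproject(fit, "baseline", k)
    slope = backproject(fit, "longitudinal", k)
    times = np.asarray(times, dtype=float)
    return base[None, :] + times[:, None] * slope[None, :]


def fit_lfpca(
    stack: ImageStack,
    *,
    fwhm_mm: float | None = None,
    n_x=0.9,
    n_w=0.9,
    max_components: int | None = 10,
    cond_bound: float = 1e10,
    center_times: bool = False,
    compute_scores: bool = True,
) -> LfpcaFit:
    """Full pipeline: (smooth) -> demean -> SVD -> moments -> eigen -> scores.

    Times are used as supplied (the loader's first-visit recentering is
    the default convention, coupling the baseline component to each
    subject's first scan).  With ``center_times=True`` the pooled mean of
    all visit times is subtracted first, so the baseline component instead
    describes the state at the mean study time; the applied offset is
    stored as ``fit.time_offset`` and ``fit.time`` holds the shifted times.
    """
    from .stack import smooth_stack

    if fwhm_mm is not None:
        stack = smooth_stack(stack, fwhm_mm)
    offset = float(stack.time.mean()) if center_times else 0.0
    times = stack.time - offset
    mean_map, centered = demean(stack)
    reduced = reduce_stack(centered, mean_map=mean_map)
    design = build_moment_design(stack.subject_id, times)
    blocks = estimate_cov_blocks(reduced, design, cond_bound=cond_bound)
    fit = eigendecompose(
        blocks, reduced, stack.subject_id, stack.visit_index, times,
        n_x=n_x, n_w=n_w, max_components=max_components,
        mask=stack.mask, voxel_size=stack.voxel_size,
    )
    fit.time_offset = offset
    if compute_scores:
        estimate_scores(fit)
    return fit


# ---------------------------------------------------------------------------
# serialization

def save_fit(fit: LfpcaFit, path) -> None:
    """Serialize a fit (eigenvalues, A-matrices, scores, SVD factors, mean
    map and mask) to a single ``.npz`` archive."""
    np.savez_compressed(
        path,
        lambda_x=fit.lambda_x, A_x0=fit.A_x0, A_x1=fit.A_x1,
        lambda_w=fit.lambda_w, A_w=fit.A_w,
        V=fit.reduced.V, S=fit.reduced.S, U=fit.reduced.U,
        mean_map=(fit.reduced.mean_map if fit.reduced.mean_map is not None
                  else np.zeros(0)),
        subject_id=fit.subject_id.astype(str),
        visit_index=fit.visit_index, time=fit.time,
        time_offset=np.float64(fit.time_offset),
        xi=(fit.xi if fit.xi is not None else np.zeros(0)),
        zeta=(fit.zeta if fit.zeta is not None else np.zeros(0)),
        mask=(fit.mask if fit.mask is not None else np.zeros(0, dtype=bool)),
        voxel_size=np.asarray(fit.voxel_size if fit.voxel_size else ()),
    )


def load_fit(path) -> LfpcaFit:
    with np.load(path, allow_pickle=False) as z:
        reduced = ReducedData(
            V=z["V"], S=z["S"], U=z["U"],
            mean_map=z["mean_map"] if z["mean_map"].size else None,
        )
        return LfpcaFit(
            lambda_x=z["lambda_x"], A_x0=z["A_x0"], A_x1=z["A_x1"],
            lambda_w=z["lambda_w"], A_w=z["A_w"], reduced=reduced,
            subject_id=z["subject_id"], visit_index=z["visit_index"],
            time=z["time"],
            time_offset=float(z["time_offset"]) if "time_offset" in z else 0.0,
            xi=z["xi"] if z["xi"].size else None,
            zeta=z["zeta"] if z["zeta"].size else None,
            mask=z["mask"] if z["mask"].size else None,
            voxel_size=tuple(z["voxel_size"]) if z["voxel_size"].size else None,
        )
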