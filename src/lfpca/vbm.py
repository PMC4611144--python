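"""Classical mass-univariate longitudinal VBM.

Per-voxel Gaussian linear mixed model with correlated random intercept and
slope (maximum likelihood), Wald inference on the fixed slope,
Benjamini-Yekutieli FDR correction (valid under arbitrary dependence) and
cluster-extent thresholding of the rejected voxels, with Table-style
cluster summaries (size, extreme t, its location, centre of gravity and
sign: enlargement for positive slopes, atrophy for negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

from .errors import DimensionError
from .mixedlm import fit_random_slope_lmm
from .stack import ImageStack, fold_map

__all__ = ["VbmResult", "fit_voxelwise", "by_fdr", "cluster_extent",
           "write_cluster_table"]


@dataclass
class VbmResult:
    """Voxelwise mixed-model results (flat p-vectors in mask order)."""

    beta0: np.ndarray
    beta1: np.ndarray
    t1: np.ndarray
    p1: np.ndarray
    q1: np.ndarray
    reject: np.ndarray
    sigma2_0: np.ndarray
    sigma2_1: np.ndarray
    sigma_01: np.ndarray
    sigma2_eps: np.ndarray
    converged: np.ndarray
    degenerate: np.ndarray
    model: np.ndarray
    fdr_level: float
    mask: np.ndarray
    voxel_size: tuple


def fit_voxelwise(
    stack: ImageStack,
    *,
    q: float = 0.05,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> VbmResult:
    """Fit y_ij(v) = beta0 + beta1 t + b_i0 + b_i1 t + eps at every voxel.

    Maximum likelihood with Wald (standard-normal) inference on the slope,
    followed by Benjamini-Yekutieli FDR at level ``q``.  Voxels where the
    full model fails fall back to a random-intercept-only fit (then pooled
    OLS with cluster-robust variance) and are flagged via ``model``.
    """
    res = fit_random_slope_lmm(stack.data, stack.subject_id, stack.time,
                               max_iter=max_iter, tol=tol)
    q1, reject = by_fdr(res.p1, q)
    return VbmResult(
        beta0=res.beta0, beta1=res.beta1, t1=res.t1, p1=res.p1,
        q1=q1, reject=reject,
        sigma2_0=res.sigma2_0, sigma2_1=res.sigma2_1,
        sigma_01=res.sigma_01, sigma2_eps=res.sigma2_eps,
        converged=res.converged, degenerate=res.degenerate, model=res.model,
        fdr_level=q, mask=stack.mask, voxel_size=stack.voxel_size,
    )


def by_fdr(pvals: np.ndarray, q: float = 0.05):
    """Benjamini-Yekutieli step-up with the harmonic-sum correction.

    Returns ``(adjusted, reject)``; adjusted values are monotone in p-rank
    and capped at 1, and are never smaller than the raw p-values.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, *_ = multipletests(pvals, alpha=q, method="fdr_by")
    return adjusted, reject


_STRUCTURES = {
    "full": ndimage.generate_binary_structure(3, 3),   # 26-neighbour (8 in 2D)
    "face": ndimage.generate_binary_structure(3, 1),   # 6-neighbour (4 in 2D)
}


def cluster_extent(
    reject: np.ndarray,
    tmap: np.ndarray,
    mask_or_stack,
    *,
    min_extent: int = 21,
    connectivity: str = "full",
) -> pd.DataFrame:
    """Connected clusters of rejected voxels, filtered by spatial extent.

    Positive-t and negative-t rejected voxels are labeled separately;
    clusters with fewer than ``min_extent`` voxels are dropped (the default
    21 keeps clusters with extent strictly more than 20 voxels).  The table
    is sorted by size descending within sign and reports the extreme t
    (max for positive clusters, min for negative), its grid location and
    the unweighted centre of gravity of the cluster.
    """
    mask = (mask_or_stack.mask if isinstance(mask_or_stack, ImageStack)
            else np.asarray(mask_or_stack, dtype=bool))
    if mask.ndim == 2:
        mask = mask[:, :, None]
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 'full' or 'face', got {connectivity!r}")
    structure = _STRUCTURES[connectivity]

    reject = np.asarray(reject)
    tmap = np.asarray(tmap, dtype=float)
    if reject.shape == mask.shape:
        rej_vol, t_vol = reject.astype(bool) & mask, np.where(mask, tmap, 0.0)
    else:
        if reject.shape != (int(mask.sum()),):
            raise DimensionError("reject map does not match the mask")
        rej_vol = fold_map(reject.astype(float), mask) > 0.5
        t_vol = fold_map(tmap, mask)

    rows = []
    for sign, name in [(1, "enlargement"), (-1, "atrophy")]:
        sel = rej_vol & ((t_vol > 0) if sign > 0 else (t_vol < 0))
        labels, nlab = ndimage.label(sel, structure=structure)
        for lab in range(1, nlab + 1):
            coords = np.argwhere(labels == lab)
            if len(coords) < min_extent:
                continue
            tvals = t_vol[tuple(coords.T)]
            ext = int(np.argmax(tvals)) if sign > 0 else int(np.argmin(tvals))
            peak = coords[ext]
            cog = coords.mean(axis=0)
            rows.append({
                "sign": name, "size": len(coords),
                "t_extreme": float(tvals[ext]),
                "peak_x": int(peak[0]), "peak_y": int(peak[1]),
                "peak_z": int(peak[2]),
                "cog_x": float(cog[0]), "cog_y": float(cog[1]),
                "cog_z": float(cog[2]),
            })
    table = pd.DataFrame(
        rows, columns=["sign", "size", "t_extreme", "peak_x", "peak_y",
                       "peak_z", "cog_x", "cog_y", "cog_z"])
    if len(table):
        table = (table.sort_values(["sign", "size"],
                                   ascending=[True, False],
                                   kind="mergesort")
                 .reset_index(drop=True))
    return table


def write_cluster_table(table: pd.DataFrame, path) -> None:
    """Write the cluster summary as a TSV file."""
    table.to_csv(path, sep="\t", index=False)
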