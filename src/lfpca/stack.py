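"""Image stacks: loading, unfolding, smoothing and folding back.

A longitudinal stack of spatially normalized scalar images (RAVENS-like
tissue-density maps, or any voxelwise measure) is kept as a single
``p x J`` matrix: ``p`` voxels inside a binary analysis mask, ``J`` images
(one per subject-visit).  Columns are grouped by subject and ordered by
visit; per-column metadata carries subject identifier, visit ordinal and
scan time.

The unfolding order is fixed: lexicographic over 0-based voxel indices with
the **first axis fastest** (Fortran ravel order).  Component maps produced
by any downstream analysis are therefore comparable across runs and can be
folded back into volumes with :func:`fold_map`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DesignError, DimensionError

__all__ = [
    "ImageStack",
    "load_stack",
    "smooth_stack",
    "fold_map",
    "unfold_volume",
    "save_stack",
    "load_covariates",
    "fwhm_to_sigma",
]

_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float, voxel_size: Sequence[float]) -> np.ndarray:
    """Per-axis Gaussian sigma (in voxels) for an isotropic FWHM in mm."""
    return fwhm_mm / _FWHM_FACTOR / np.asarray(voxel_size, dtype=float)


def _as_volume(mask: np.ndarray) -> np.ndarray:
    """Promote 2D arrays to degenerate 3D volumes (third axis of size 1)."""
    a = np.asarray(mask)
    if a.ndim == 2:
        a = a[:, :, None]
    if a.ndim != 3:
        raise DimensionError(f"expected a 2D or 3D volume, got ndim={a.ndim}")
    return a


def _mask_order(mask: np.ndarray) -> np.ndarray:
    """Flat (Fortran-order) indices of the mask voxels, in unfolding order."""
    return np.flatnonzero(np.asarray(mask, dtype=bool).ravel(order="F"))


def unfold_volume(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Extract the masked voxels of ``volume`` as a p-vector in canonical order."""
    volume = _as_volume(volume)
    mask = _as_volume(mask).astype(bool)
    if volume.shape != mask.shape:
        raise DimensionError(
            f"volume shape {volume.shape} does not match mask shape {mask.shape}"
        )
    return volume.ravel(order="F")[_mask_order(mask)]


def fold_map(vector: np.ndarray, stack_or_mask, fill: float = 0.0) -> np.ndarray:
    """Fold a p-vector back into a volume, background voxels set to ``fill``.

    Round-trips exactly with the unfolding used by :func:`load_stack`.
    """
    mask = stack_or_mask.mask if isinstance(stack_or_mask, ImageStack) else stack_or_mask
    mask = _as_volume(mask).astype(bool)
    vector = np.asarray(vector)
    idx = _mask_order(mask)
    if vector.shape != (idx.size,):
        raise DimensionError(
            f"vector has length {vector.shape}, mask has {idx.size} voxels"
        )
    out = np.full(mask.size, fill, dtype=float)
    out[idx] = vector
    return out.reshape(mask.shape, order="F")


@dataclass
class ImageStack:
    """Masked, unfolded longitudinal image matrix with per-column metadata.

    Attributes
    ----------
    data : (p, J) float array
        One column per subject-visit, rows in canonical mask order.
    subject_id, visit_index, time : (J,) arrays
        Per-column metadata.  Columns are grouped by subject with visits in
        ascending order; every subject has at least two visits.
    mask : (nx, ny, nz) bool array
        Binary analysis mask with exactly p nonzero voxels.
    voxel_size : tuple of float
        Physical voxel edge lengths in mm.
    """

    data: np.ndarray
    subject_id: np.ndarray
    visit_index: np.ndarray
    time: np.ndarray
    mask: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.subject_id = np.asarray(self.subject_id)
        self.visit_index = np.asarray(self.visit_index, dtype=int)
        self.time = np.asarray(self.time, dtype=float)
        self.mask = _as_volume(self.mask).astype(bool)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        p, j = self.data.shape
        if int(self.mask.sum()) != p:
            raise DimensionError(
                f"mask has {int(self.mask.sum())} voxels but data has {p} rows"
            )
        for arr, name in [(self.subject_id, "subject_id"),
                          (self.visit_index, "visit_index"),
                          (self.time, "time")]:
            if arr.shape != (j,):
                raise DimensionError(f"{name} must have one entry per column")
        if not np.all(np.isfinite(self.data)):
            r, c = np.argwhere(~np.isfinite(self.data))[0]
            raise DataError(f"non-finite value at voxel {r}, column {c}")
        # columns grouped by subject, visits ascending, >= 2 visits each
        seen = set()
        for sid, sl in self.subject_blocks():
            if sid in seen:
                raise DesignError(f"columns of subject {sid!r} are not contiguous")
            seen.add(sid)
            if sl.stop - sl.start < 2:
                raise DesignError(f"subject {sid!r} has a single visit")
            v = self.visit_index[sl]
            if np.any(np.diff(v) <= 0):
                raise DesignError(f"visits of subject {sid!r} are not ascending")

    # -- structure ---------------------------------------------------------
    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_images(self) -> int:
        return self.data.shape[1]

    @property
    def grid_shape(self) -> tuple:
        return self.mask.shape

    @property
    def subjects(self) -> np.ndarray:
        """Unique subject ids in column order."""
        _, first = np.unique(self.subject_id, return_index=True)
        return self.subject_id[np.sort(first)]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subject_blocks(self):
        """Yield ``(subject_id, slice)`` pairs over contiguous column blocks."""
        sid = self.subject_id
        start = 0
        for j in range(1, len(sid) + 1):
            if j == len(sid) or sid[j] != sid[start]:
                yield sid[start], slice(start, j)
                start = j

    def fold(self, vector: np.ndarray, fill: float = 0.0) -> np.ndarray:
        return fold_map(vector, self.mask, fill=fill)

    def with_data(self, data: np.ndarray) -> "ImageStack":
        return replace(self, data=data)


def _read_design(design) -> pd.DataFrame:
    if isinstance(design, (str, Path)):
        sep = "\t" if str(design).endswith((".tsv", ".txt")) else ","
        design = pd.read_csv(design, sep=sep)
    design = pd.DataFrame(design).copy()
    missing = {"subject_id", "visit", "time"} - set(design.columns)
    if missing:
        raise DesignError(f"design table lacks columns: {sorted(missing)}")
    return design


def load_stack(
    image_paths: Sequence,
    mask_path,
    design,
    *,
    recenter_times: bool = True,
) -> ImageStack:
    """Assemble an :class:`ImageStack` from volume files and a design table.

    Parameters
    ----------
    image_paths : sequence of paths
        One NIfTI volume per subject-visit.  Row ``i`` of ``design``
        describes ``image_paths[i]``.
    mask_path : path
        Binary mask volume; all images must share its grid and voxel size.
    design : DataFrame or CSV/TSV path
        Columns ``subject_id``, ``visit``, ``time`` (and optionally ``file``,
        ignored for ordering).
    recenter_times : bool
        If True (default), re-express each subject's times relative to its
        first visit so that t_i1 = 0, the convention used by all downstream
        fits (the baseline component is the state at t = 0).

    The returned columns are sorted canonically by ``(subject_id, visit)``,
    so any permutation of the input files yields the identical stack.
    """
    import nibabel as nib

    design = _read_design(design)
    if len(design) != len(image_paths):
        raise DesignError(
            f"{len(image_paths)} images but {len(design)} design rows"
        )

    mask_img = nib.load(str(mask_path))
    mask = _as_volume(np.asanyarray(mask_img.dataobj) > 0)
    zooms = mask_img.header.get_zooms()[:3]
    voxel_size = tuple(float(z) for z in zooms) if len(zooms) == 3 else (
        float(zooms[0]), float(zooms[1]), 1.0)
    idx = _mask_order(mask)

    cols = np.empty((idx.size, len(image_paths)), dtype=float)
    for j, path in enumerate(image_paths):
        img = nib.load(str(path))
        vol = _as_volume(np.asanyarray(img.dataobj).astype(float))
        if vol.shape != mask.shape:
            raise DimensionError(
                f"{path}: shape {vol.shape} does not match mask {mask.shape}"
            )
        cols[:, j] = vol.ravel(order="F")[idx]

    order = design.reset_index(drop=True).sort_values(
        ["subject_id", "visit"], kind="mergesort"
    ).index.to_numpy()
    design = design.iloc[order].reset_index(drop=True)
    cols = cols[:, order]

    bad = np.argwhere(~np.isfinite(cols))
    if bad.size:
        r, c = bad[0]
        raise DataError(
            f"non-finite voxel inside mask: voxel {r} of image "
            f"{design['subject_id'].iloc[c]!r} visit {design['visit'].iloc[c]}"
        )

    times = design["time"].to_numpy(dtype=float)
    if recenter_times:
        for sid in pd.unique(design["subject_id"]):
            sel = (design["subject_id"] == sid).to_numpy()
            times[sel] = times[sel] - times[sel].min()

    return ImageStack(
        data=cols,
        subject_id=design["subject_id"].to_numpy(),
        visit_index=design["visit"].to_numpy(dtype=int),
        time=times,
        mask=mask,
        voxel_size=voxel_size,
    )


def smooth_stack(stack: ImageStack, fwhm_mm: float, *, truncate: float = 6.0) -> ImageStack:
    """Smooth every image with an isotropic Gaussian of the given FWHM (mm).

    Smoothing is applied on the full grid with zero padding (images folded
    with background 0), then re-masked.  Axes of length 1 (degenerate 2D
    volumes) are left untouched.
    """
    from scipy import ndimage

    if not fwhm_mm > 0:
        raise ValueError(f"fwhm_mm must be positive, got {fwhm_mm}")
    sigma = fwhm_to_sigma(fwhm_mm, stack.voxel_size)
    sigma = np.where(np.array(stack.grid_shape) > 1, sigma, 0.0)
    out = np.empty_like(stack.data)
    for j in range(stack.n_images):
        vol = stack.fold(stack.data[:, j])
        sm = ndimage.gaussian_filter(vol, sigma=sigma, mode="constant",
                                     truncate=truncate)
        out[:, j] = unfold_volume(sm, stack.mask)
    return stack.with_data(out)


def save_stack(stack: ImageStack, outdir, *, prefix: str = "img") -> dict:
    """Write a stack as per-image NIfTI volumes plus design table and mask.

    Returns a dict with the written paths (``images``, ``mask``, ``design``).
    """
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(stack.voxel_size) + [1.0])
    mask_path = outdir / "mask.nii.gz"
    nib.save(nib.Nifti1Image(stack.mask.astype(np.uint8), affine), mask_path)
    rows, paths = [], []
    for j in range(stack.n_images):
        name = f"{prefix}_{j:04d}.nii.gz"
        nib.save(nib.Nifti1Image(stack.fold(stack.data[:, j]), affine),
                 outdir / name)
        paths.append(outdir / name)
        rows.append({
            "file": name,
            "subject_id": stack.subject_id[j],
            "visit": int(stack.visit_index[j]),
            "time": float(stack.time[j]),
        })
    design_path = outdir / "design.csv"
    pd.DataFrame(rows).to_csv(design_path, index=False)
    return {"images": paths, "mask": mask_path, "design": design_path}


def load_covariates(table, stack: ImageStack | None = None) -> pd.DataFrame:
    """Read a per-subject covariate table (CSV/TSV or DataFrame).

    One row per subject, indexed by ``subject_id``.  If ``stack`` is given,
    the subject sets must agree.
    """
    if isinstance(table, (str, Path)):
        sep = "\t" if str(table).endswith((".tsv", ".txt")) else ","
        table = pd.read_csv(table, sep=sep)
    df = pd.DataFrame(table).copy()
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
    if df.index.has_duplicates:
        raise DesignError("covariate table has duplicated subject rows")
    if stack is not None:
        have, want = set(df.index), set(stack.subjects.tolist())
        if have != want:
            raise DesignError(
                f"covariate subjects differ from stack subjects: "
                f"extra={sorted(have - want)}, missing={sorted(want - have)}"
            )
    return df
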