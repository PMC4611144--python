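"""Phantom generators for longitudinal morphometry experiments.

Two generators are provided:

:func:`simulate_phantom`
    A 2D phantom mimicking a longitudinal stack of RAVENS-like
    tissue-density images with four canonical structures — background (B),
    a big white-matter square (W), a small ventricle square (V) inside it
    and a gray-matter rectangle (G) at the bottom.  Per subject it draws
    five latent quantities: a W-intensity deviation (cross-sectional
    intensity variation), a rigid integer shift of the whole rendered image
    (registration error, constant across the subject's visits), symmetric
    integer dilations/erosions of V and G (cross-sectional size variation)
    and a longitudinal factor that drives a linear intensity change over
    visits: ventricles brighten (enlargement) while gray and white matter
    darken (atrophy).  Independent Gaussian pixel noise is added per visit.
    Full ground truth is returned for recovery testing.

:func:`simulate_from_model`
    Draws data exactly from the truncated random intercept/slope component
    model y~_ij = Phi_X0 xi_i + t_ij Phi_X1 xi_i + Phi_W zeta_ij with
    user-supplied orthonormal components and score variances.

Both generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .stack import ImageStack

__all__ = ["PhantomParams", "simulate_phantom", "simulate_from_model",
           "structure_masks"]


@dataclass
class PhantomParams:
    """Parameters of the 2D longitudinal phantom.

    Geometry is expressed as fractions of the grid so that smaller grids
    (e.g. 100 x 100 for quick runs) preserve the layout.  Intensities are
    dimensionless RAVENS-like units.

    The size deviations are symmetric Rademacher draws: each subject's V
    (and, independently, G) is either dilated or eroded by the stated
    number of pixels, with equal probability.  Longitudinal change has two
    parts: a deterministic population trend (ventricles brighten, gray and
    white matter darken, per year) shared by every subject, and a zero-mean
    Gaussian subject factor whose loadings couple extra ventricular change
    with opposite-signed gray/white-matter change — the phantom's
    subject-specific longitudinal component.
    """

    grid: tuple = (200, 200)
    n_subjects: int = 50
    visit_times: tuple = (0.0, 1.0, 2.0, 3.0)
    # structure geometry (fractions of the grid)
    w_bounds: tuple = (0.20, 0.80)         # big square (both axes)
    v_half_frac: float = 0.075             # ventricle half-width
    g_row_bounds: tuple = (0.84, 0.92)     # gray rectangle rows
    g_col_bounds: tuple = (0.30, 0.70)     # gray rectangle cols
    # base intensities
    bg_intensity: float = 0.0
    white_intensity: float = 100.0
    ventricle_intensity: float = 60.0
    gray_intensity: float = 80.0
    # cross-sectional (baseline) variation
    w_intensity_sd: float = 10.0           # subject W-intensity deviation
    shift_max: int = 1                     # rigid shift, uniform integers in [-max, max]
    v_size_dev: int = 1                    # +/- pixels of V dilation/erosion
    g_size_dev: int = 1                    # +/- pixels of G dilation/erosion
    # deterministic population trend (intensity per year)
    trend_v: float = 20.0                  # ventricle brightening (enlargement)
    trend_g: float = -1.0                  # gray-matter darkening (atrophy)
    trend_w: float = -0.5                  # white-matter darkening (atrophy)
    # subject-specific longitudinal variation (per unit time, per unit factor)
    long_factor_mean: float = 0.0
    long_factor_sd: float = 20.0
    load_v: float = 1.0                    # extra ventricle change per unit factor
    load_g: float = -4.0                   # extra gray-matter change (opposite sign)
    load_w: float = -1.0                   # extra white-matter change
    # visit-specific noise
    noise_sd: float = 8.0
    noise_smooth_sigma: float = 0.0        # optional spatial smoothing of the noise
    seed: int = 0

    def validate(self) -> None:
        n0, n1 = self.grid
        for sd in [self.w_intensity_sd, self.long_factor_sd, self.noise_sd]:
            if sd < 0:
                raise ValidationError("standard deviations must be >= 0")
        if self.shift_max < 0 or self.v_size_dev < 0 or self.g_size_dev < 0:
            raise ValidationError("shift_max and size deviations must be >= 0")
        b = self._bounds()
        s = self.shift_max
        for (r0, r1, c0, c1) in [b["w"], b["g_outer"]]:
            if r0 - s < 0 or r1 + s > n0 or c0 - s < 0 or c1 + s > n1:
                raise ValidationError(
                    "structure leaves the grid after the maximal rigid shift"
                )
        wr0, wr1, wc0, wc1 = b["w"]
        vr0, vr1, vc0, vc1 = b["v_outer"]
        if not (wr0 < vr0 and vr1 < wr1 and wc0 < vc0 and vc1 < wc1):
            raise ValidationError("V (after dilation) must lie strictly inside W")

    def _bounds(self) -> dict:
        n0, n1 = self.grid
        w0, w1 = (int(round(f * n0)) for f in self.w_bounds)
        c = n0 // 2
        h = int(round(self.v_half_frac * n0))
        g_r = tuple(int(round(f * n0)) for f in self.g_row_bounds)
        g_c = tuple(int(round(f * n1)) for f in self.g_col_bounds)
        return {
            "w": (w0, w1, w0, w1),
            "v": (c - h, c + h, c - h, c + h),
            "v_outer": (c - h - self.v_size_dev, c + h + self.v_size_dev,
                        c - h - self.v_size_dev, c + h + self.v_size_dev),
            "g": (g_r[0], g_r[1], g_c[0], g_c[1]),
            "g_outer": (g_r[0] - self.g_size_dev, g_r[1] + self.g_size_dev,
                        g_c[0] - self.g_size_dev, g_c[1] + self.g_size_dev),
        }


def _box(grid, r0, r1, c0, c1) -> np.ndarray:
    m = np.zeros(grid, dtype=bool)
    m[r0:r1, c0:c1] = True
    return m


def structure_masks(params: PhantomParams) -> dict:
    """Base-geometry boolean masks for B, W (excluding V), V and G."""
    b = params._bounds()
    v = _box(params.grid, *b["v"])
    w = _box(params.grid, *b["w"]) & ~v
    g = _box(params.grid, *b["g"])
    bg = ~(v | w | g)
    return {"B": bg, "W": w, "V": v, "G": g}


def _render_modes(params: PhantomParams):
    """Template and additive latent-mode maps of the noiseless phantom."""
    b = params._bounds()
    masks = structure_masks(params)
    template = (params.bg_intensity * masks["B"]
                + params.white_intensity * masks["W"]
                + params.ventricle_intensity * masks["V"]
                + params.gray_intensity * masks["G"])

    # size overlays: dilation turns a boundary ring of the host tissue into
    # the structure's tissue; erosion does the reverse on an inner ring
    sv = params.v_size_dev
    v_out = _box(params.grid, *[x + d for x, d in
                                zip(b["v"], (-sv, sv, -sv, sv))]) & ~_box(params.grid, *b["v"])
    v_in = _box(params.grid, *b["v"]) & ~_box(
        params.grid, *[x + d for x, d in zip(b["v"], (sv, -sv, sv, -sv))])
    dv = params.ventricle_intensity - params.white_intensity
    overlay_v = {+1: dv * v_out.astype(float), -1: -dv * v_in.astype(float)}

    sg = params.g_size_dev
    g_out = _box(params.grid, *[x + d for x, d in
                                zip(b["g"], (-sg, sg, -sg, sg))]) & ~_box(params.grid, *b["g"])
    g_in = _box(params.grid, *b["g"]) & ~_box(
        params.grid, *[x + d for x, d in zip(b["g"], (sg, -sg, sg, -sg))])
    dg = params.gray_intensity - params.bg_intensity
    overlay_g = {+1: dg * g_out.astype(float), -1: -dg * g_in.astype(float)}

    trend_map = (params.trend_v * masks["V"]
                 + params.trend_g * masks["G"]
                 + params.trend_w * masks["W"]).astype(float)
    long_map = (params.load_v * masks["V"]
                + params.load_g * masks["G"]
                + params.load_w * masks["W"]).astype(float)
    return (template, masks["W"].astype(float), overlay_v, overlay_g,
            trend_map, long_map)


def simulate_phantom(params: PhantomParams | None = None, *, seed: int | None = None):
    """Generate the longitudinal 2D phantom stack and its ground truth.

    Returns ``(stack, truth)`` where ``truth`` is a one-row-per-subject
    DataFrame with the latent variables (W-intensity deviation, rigid shift,
    V/G size deviations in signed pixels, longitudinal factor).
    """
    params = params or PhantomParams()
    params.validate()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    n0, n1 = params.grid
    (template, m_w, overlay_v, overlay_g,
     trend_map, long_map) = _render_modes(params)
    times = np.asarray(params.visit_times, dtype=float)
    nvis = times.size
    N = params.n_subjects

    w_dev = rng.normal(0.0, params.w_intensity_sd, N)
    shifts = rng.integers(-params.shift_max, params.shift_max + 1, size=(N, 2))
    v_sign = np.where(rng.random(N) < 0.5, -1, 1)
    g_sign = np.where(rng.random(N) < 0.5, -1, 1)
    factor = rng.normal(params.long_factor_mean, params.long_factor_sd, N)

    data = np.empty((n0 * n1, N * nvis))
    sids, visits, tcol = [], [], []
    col = 0
    for i in range(N):
        base = (template + w_dev[i] * m_w)
        if params.v_size_dev:
            base = base + overlay_v[int(v_sign[i])]
        if params.g_size_dev:
            base = base + overlay_g[int(g_sign[i])]
        # registration error is a baseline-only artifact: the subject's
        # (mis)registered baseline anatomy is shifted, while the modeled
        # longitudinal change lives in template space
        base_shifted = np.roll(base, (int(shifts[i, 0]), int(shifts[i, 1])),
                               axis=(0, 1))
        for j, t in enumerate(times):
            img = base_shifted + t * (trend_map + factor[i] * long_map)
            if params.noise_sd > 0:
                noise = rng.normal(0.0, params.noise_sd, (n0, n1))
                if params.noise_smooth_sigma > 0:
                    from scipy import ndimage
                    noise = ndimage.gaussian_filter(
                        noise, params.noise_smooth_sigma, mode="constant")
                img = img + noise
            data[:, col] = img.ravel(order="F")
            sids.append(f"S{i + 1:03d}")
            visits.append(j + 1)
            tcol.append(t)
            col += 1

    mask = np.ones((n0, n1, 1), dtype=bool)
    stack = ImageStack(
        data=data, subject_id=np.array(sids), visit_index=np.array(visits),
        time=np.array(tcol), mask=mask, voxel_size=(1.0, 1.0, 1.0),
    )
    truth = pd.DataFrame({
        "subject_id": [f"S{i + 1:03d}" for i in range(N)],
        "w_intensity_dev": w_dev,
        "shift_dx": shifts[:, 0],
        "shift_dy": shifts[:, 1],
        "v_size_dev": v_sign * params.v_size_dev,
        "g_size_dev": g_sign * params.g_size_dev,
        "long_factor": factor,
        "noise_sd": params.noise_sd,
    })
    return stack, truth


def simulate_from_model(
    phi_x0: np.ndarray,
    phi_x1: np.ndarray,
    phi_w: np.ndarray,
    lambda_x,
    lambda_w,
    *,
    n_subjects: int,
    visit_times,
    seed: int = 0,
    mean_map: np.ndarray | None = None,
    orth_tol: float = 1e-8,
):
    """Draw a stack exactly from the truncated component model.

    The stacked columns (phi_x0[:, k]; phi_x1[:, k]) must be orthonormal,
    as must the columns of ``phi_w``.  Scores are independent zero-mean
    Gaussians with variances ``lambda_x`` / ``lambda_w``.

    Returns ``(stack, truth)`` with ``truth = {"xi": (N, N_X), "zeta": (J, N_W)}``.
    """
    phi_x0 = np.atleast_2d(np.asarray(phi_x0, dtype=float))
    phi_x1 = np.atleast_2d(np.asarray(phi_x1, dtype=float))
    phi_w = np.atleast_2d(np.asarray(phi_w, dtype=float))
    if phi_x0.shape[0] == 1:
        phi_x0, phi_x1, phi_w = phi_x0.T, phi_x1.T, phi_w.T
    lambda_x = np.atleast_1d(np.asarray(lambda_x, dtype=float))
    lambda_w = np.atleast_1d(np.asarray(lambda_w, dtype=float))
    p = phi_x0.shape[0]

    stacked = np.vstack([phi_x0, phi_x1])
    if stacked.shape[1]:
        gram = stacked.T @ stacked
        if not np.allclose(gram, np.eye(stacked.shape[1]), atol=orth_tol):
            raise ValidationError(
                "stacked subject-specific components are not orthonormal")
    if phi_w.shape[1]:
        gram = phi_w.T @ phi_w
        if not np.allclose(gram, np.eye(phi_w.shape[1]), atol=orth_tol):
            raise ValidationError("visit-specific components are not orthonormal")

    rng = np.random.default_rng(seed)
    times = np.asarray(visit_times, dtype=float)
    nvis = times.size
    J = n_subjects * nvis
    xi = rng.normal(size=(n_subjects, lambda_x.size)) * np.sqrt(lambda_x)
    zeta = rng.normal(size=(J, lambda_w.size)) * np.sqrt(lambda_w)

    data = np.empty((p, J))
    sids, visits, tcol = [], [], []
    col = 0
    for i in range(n_subjects):
        for j, t in enumerate(times):
            y = phi_x0 @ xi[i] + t * (phi_x1 @ xi[i]) + phi_w @ zeta[col]
            if mean_map is not None:
                y = y + mean_map
            data[:, col] = y
            sids.append(f"S{i + 1:03d}")
            visits.append(j + 1)
            tcol.append(t)
            col += 1

    stack = ImageStack(
        data=data, subject_id=np.array(sids), visit_index=np.array(visits),
        time=np.array(tcol), mask=np.ones((p, 1, 1), dtype=bool),
        voxel_size=(1.0, 1.0, 1.0),
    )
    return stack, {"xi": xi, "zeta": zeta}
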