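# Methods

## The model

Each spatially normalized image of subject *i* at visit *j* (scan time
*t_ij*, in years since the subject's first scan) is unfolded into a
*p*-vector *y_ij*.  After subtracting the voxelwise sample mean over all
images, the residual images are modeled as a random intercept / random
slope process plus a visit-specific deviation:

    y~_ij(v) = x_i0(v) + t_ij x_i1(v) + W_ij(v),

where (x_i0, x_i1) is the subject-specific imaging process (baseline level
and linear rate of change, correlated across the two halves) and W_ij is a
zero-mean visit-specific deviation uncorrelated with it.  Karhunen–Loève
truncation of the two covariance operators gives

    y~_ij = Phi_X0 xi_i + t_ij Phi_X1 xi_i + Phi_W zeta_ij,

with stacked orthonormal subject-specific eigenimages
(Phi_X0_k; Phi_X1_k), eigenvalues lambda_X (descending), and orthonormal
visit-specific eigenimages Phi_W with eigenvalues lambda_W.  A component's
**longitudinal ratio** ||Phi_X1_k||^2 / (||Phi_X0_k||^2 + ||Phi_X1_k||^2)
lives on [0, 1]: 0 is a pure cross-sectional (baseline) pattern, 1 a pure
rate-of-change pattern.

## Estimation

**Moment identity.**  For two visits of the same subject,

    E[y~_ij1 y~_ij2'] = K00 + t_ij2 K01 + t_ij1 K10
                        + t_ij1 t_ij2 K11 + delta_j1j2 KW,

so regressing the pair outer products on
f = (1, t_ij2, t_ij1, t_ij1 t_ij2, delta)' over all m = sum_i J_i^2
ordered within-subject pairs recovers the covariance blocks by ordinary
least squares, K^ = Y F'(F F')^-1, without distributional assumptions.
Identifiability requires at least five linearly independent f-vectors:
two visits per subject at shared times are not enough (this raises a
singular-design error); three visits are.

**Dimension reduction.**  The demeaned data matrix is factored by a thin
SVD, y~ = V S U'.  Since V has orthonormal columns, multiplying the model
by V' preserves the entire correlation structure; the moment regression,
the eigendecomposition of the stacked 2r x 2r matrix
[[K00, K01], [K10, K11]] and of KW, and the score estimation are all done
on the r-dimensional reduced images w_j = S U'_j (r <= J - 1).  Full-space
eigenimages are recovered as Phi = V A.  The OLS response is accumulated
subject-block by subject-block (K_q += W_i C_q W_i'), so memory scales
with r^2, never with p^2.  Tests assert exact agreement (to 1e-8 relative)
with a brute-force p^2 x m full-space fit on small problems.

**Truncation.**  Method-of-moments covariance estimates need not be
positive semidefinite; eigenvalues <= 0 are discarded outright (never
clipped into the retained set).  The default keeps components up to 90% of
the summed positive eigenvalue mass, capped at 10 per process; both knobs
are user-settable (an integer is a count, a float a variance fraction).
Eigenvector signs follow the convention that the largest-magnitude entry
of each stacked eigenvector is positive.

**Scores.**  Scores are estimated per subject by the unweighted
least-squares (BLUP-style) formula omega^_i = (B'B)^-1 B' vec(y~_i) with
per-visit design blocks [A_X0 + t_ij A_X1 | block-diagonal A_W]; a
rank-deficient design falls back to the minimum-norm solution with a
warning.  No eigenvalue-weighted ridge term is added, for fidelity to the
estimator as stated; by linearity the reduced- and full-space computations
coincide (asserted to 1e-9 in tests).

**Time parametrization.**  The loader re-expresses each subject's times
relative to its first visit (t_i1 = 0) by default, so the baseline
component is the state at the subject's first scan.  Because the mean
surface is the *time-constant* sample mean over all images, a population
mean trend leaves a deterministic (t - t_bar)-shaped residual that the
moment estimator books as covariance: a rank-one pseudo-component with
longitudinal ratio 1/(1 + t_bar^2) appears whenever the data carry a
shared trend.  This is a property of the method as specified (a
time-varying mean surface is out of scope), not of the implementation;
`fit_lfpca(center_times=True)` re-centers times at the pooled mean, which
relocates but cannot remove the artifact.  The phantom's design (below)
keeps the shared-trend direction nearly orthogonal to the
subject-variation direction so the two are cleanly separated in practice.

## Voxelwise mixed-model VBM baseline

For comparison, the classical mass-univariate analysis fits, at every
voxel,

    y_ij = beta0 + beta1 t_ij + b_i0 + b_i1 t_ij + eps_ij,
    (b_i0, b_i1) ~ N(0, G),  eps_ij ~ N(0, sigma_eps^2),

by maximum likelihood.  The fitter is a vectorized EM algorithm: all
voxels iterate simultaneously as trailing array axes, with subjects
grouped by identical visit-time vectors so the marginal covariance is
shared within a group.  EM keeps G positive semidefinite and the residual
variance positive; convergence is declared at a relative log-likelihood
change below 1e-8 (default cap 500 iterations).  Voxels where the full
model yields non-finite results are refitted with a random intercept only,
then with pooled OLS and a cluster-robust (by subject) variance; the
`model` code records the estimator used.  The implementation is
cross-checked against statsmodels MixedLM (ML) to 1e-4 on the slope and
1e-3 on the log-likelihood.

Inference on the fixed slope is Wald: t1 = beta1^/SE referred to the
standard normal.  No degrees-of-freedom correction is applied (none is
prescribed for ML-based VBM here); with 50 subjects this makes the test
slightly liberal (~0.055 at nominal 0.05), which the seeded null
simulation quantifies.  Multiplicity is handled by Benjamini–Yekutieli
FDR (valid under arbitrary dependence, harmonic-sum correction; default
q = 0.05), followed by cluster-extent filtering of the rejected voxels:
BY rejection first, then connected components (26-neighbor in 3D,
8-neighbor in 2D by default) computed separately for positive and
negative t, keeping clusters of more than 20 voxels (`min_extent = 21`).
The cluster table reports size, extreme t, its grid location, and the
unweighted centre of gravity of each cluster.

## The phantom

The phantom emulates a longitudinal study of tissue-density (RAVENS-like)
maps on a 200 x 200 grid (all geometry is specified as grid fractions, so
a 100 x 100 grid preserves the layout at quarter cost): background B = 0,
a white-matter square W = 100 over the central 60% of the grid, a
ventricle square V = 60 strictly inside it, and a gray-matter rectangle
G = 80 at the bottom.  Defaults: 50 subjects, 4 visits at t = 0, 1, 2, 3
years.

Per subject five latent quantities are drawn:

- **W-intensity deviation** ~ N(0, 10^2): cross-sectional intensity
  variability of white matter.
- **Rigid shift** (dx, dy), uniform integers in [-1, 1]: registration
  error.  The subject's rendered *baseline* anatomy is shifted as a whole;
  the shift is constant over the subject's visits, i.e. a purely
  cross-sectional artifact.
- **V and G size deviations**: symmetric +-1-pixel dilation/erosion,
  rendered as additive boundary-ring overlays.  The deviations are
  two-valued (Rademacher) by design: a binary latent contributes exactly
  one direction to the demeaned stack regardless of how nonlinearly it
  enters the rendering, which keeps the noiseless phantom at rank <= 5
  (a property the tests assert); a multi-valued integer dilation would
  break that.
- **Longitudinal factor** f ~ N(0, 20^2) with loadings (+1, -4, -1) on
  V/G/W intensity per factor-year: subjects differ in their rate of
  change, coupling extra ventricular brightening with gray/white
  darkening.  This is the longitudinal component proper.

On top of the factor, a **deterministic population trend**
(+20, -1, -0.5)/year on V/G/W makes every subject's ventricles brighten
(enlargement, in density-map convention) and gray/white matter darken
(atrophy).  Keeping the trend direction (ventricle-dominated) nearly
orthogonal to the factor's loading direction (gray-matter-dominated) is
deliberate: the trend is what the voxelwise LMM's fixed slope detects,
the factor is what the decomposition's longitudinal component recovers,
and tying both to one direction would couple the two analyses through the
shared-trend artifact described above.  Finally i.i.d. Gaussian visit
noise (sd 8, optionally smoothed) is added per pixel.

The magnitudes were calibrated so that, per the intended study design,
(i) the voxelwise LMM detects the ventricular trend (slope z ~ 7 against
a Benjamini–Yekutieli threshold near 4 on a 10^4-voxel grid) but not the
G/W trends (|z| < 2, drowned by visit noise and slope heterogeneity), and
(ii) the longitudinal eigenvalue (~2.5e6 at 100 x 100) is well separated
from the registration-shift eigenvalue band (~9e5) and the other baseline
modes, so eigenvector mixing cannot blur the longitudinal/baseline
attribution.  Under these defaults the decomposition yields exactly one
component with longitudinal ratio > 0.5, its scores correlate with the
true factor at |r| > 0.99, and shift-driven components keep ratios below
0.2 — verified across 20 generator seeds, not tuned to any single one.

What the phantom does not emulate: realistic anatomy, spatially
correlated registration error (shifts are global and integer), nonlinear
trajectories, scanner drift, or spatially structured noise (unless the
smoothing knob is used).  Passing tests therefore demonstrate the
estimator's algebra and its separation behavior under the stated
generative model, not performance on real morphometry data.

## Model-based generator

`simulate_from_model` draws data exactly from the truncated component
model with user-supplied orthonormal components and score variances
(orthonormality is validated to 1e-8).  It backs the recovery tests:
at N = 100 subjects, 4 visits, two subject and two visit components with
3:1 eigenvalue ratios, the fit recovers component subspaces to < 5
degrees of principal angle and scores to |r| > 0.95.  Estimated
eigenvalues are compared against the *realized* score variances of the
generated dataset: the estimator tracks those to a few percent, whereas
any single replicate's realized variance differs from the population
value by O(sqrt(2/N)) ~ 14%, so a population comparison at this sample
size would measure Monte-Carlo luck rather than estimator quality.

## Numerical choices

- SVD rank: singular values above max(p, J) * eps * s_max.
- Moment design conditioning: cond(F F') must stay below 1e10 (error
  otherwise, reporting the condition number).
- Smoothing: isotropic Gaussian, sigma = FWHM/(2 sqrt(2 ln 2)) per axis in
  voxel units, applied to the full grid with zero padding before
  re-masking (kernel truncated at 6 sigma).  Consequently constants are
  preserved only where the kernel support stays inside the grid; the
  property tests use interior masks.  Axes of length 1 (2D inputs as
  degenerate volumes) are not smoothed.
- Degenerate voxels (zero response variance) are flagged and get p = 1 in
  the VBM branch; an all-zero stack raises a degenerate-data error in the
  decomposition branch.
- EM residual variance is floored at 1e-10 times the per-voxel data
  variance so residual-free (deterministic) voxels remain numerically
  stable; their fixed effects are still recovered exactly.

## Problem sizes

The test suite and the acceptance script run the phantom at 100 x 100
(10^4 voxels, 200 images), recovery at p = 400 with 100 subjects, the
null calibration at 2,000 voxels with 200 subjects, and the brute-force
oracle comparisons at p <= 40, sizes at which the full-space oracles are
exact and the complete run takes about two minutes on one core.  The
package itself has no such limits; the 200 x 200 default phantom and
stacks with ~10^5 voxels run in seconds because everything operates in
the J-dimensional reduced space.

## Known limitations

- The mean surface is the overall sample mean; population mean trends
  leak into the estimated covariance as a rank-one pseudo-component (see
  above).  A visit-wise or smooth time-varying mean is out of scope.
- Wald-normal inference is slightly liberal at small N; no Satterthwaite
  or Kenward–Roger correction is provided.
- Scores use the plain least-squares formula; for components with small
  eigenvalues relative to noise this is noisier than a shrinkage
  (eigenvalue-weighted) predictor would be.
- Nonlinear time trajectories are not modeled.
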