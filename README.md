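# lfpca — longitudinal functional PCA and mixed-model VBM for image stacks

`lfpca` analyzes longitudinal stacks of spatially normalized scalar images
— tissue-density (RAVENS-style) maps, modulated gray-matter maps, or any
voxelwise measure observed repeatedly per subject.  It is aimed at
neuroimaging researchers who want to go beyond mass-univariate
voxel-based morphometry (VBM) when longitudinal change is a small
fraction of the overall variability, as in normal aging and chronic
disease, and when registration error contaminates the maps.

## What it computes

**High-dimensional longitudinal functional PCA.**  After removing the
voxelwise sample mean, each image is modeled as

    y~_ij = Phi_X0 xi_i + t_ij Phi_X1 xi_i + Phi_W zeta_ij,

a subject-specific random imaging intercept (baseline pattern Phi_X0) and
random imaging slope (longitudinal pattern Phi_X1) sharing scores xi_i,
plus a visit-specific deviation Phi_W with scores zeta_ij.  Covariance
blocks are estimated by a method of moments — OLS of within-subject image
outer products on f = (1, t_ij2, t_ij1, t_ij1 t_ij2, delta)' — and
eigendecomposed.  Everything runs in the J-dimensional space of a thin
SVD (y~ = V S U'), so 10^5-voxel stacks fit in seconds; eigenimages are
recovered as Phi = V A.  Each subject-specific component reports its
variance share and its *longitudinal ratio*
||Phi_X1_k||^2 / (||Phi_X0_k||^2 + ||Phi_X1_k||^2): near 0 for
cross-sectional patterns (anatomy, registration error), near 1 for pure
rates of change.  Scores are best-linear-unbiased-prediction estimates
usable in downstream regressions.

**Classical longitudinal VBM baseline.**  Per voxel, the Gaussian linear
mixed model y_ij = beta0 + beta1 t + b_i0 + b_i1 t + eps (correlated
random intercept and slope, maximum likelihood via a vectorized EM that
fits all voxels at once), Wald tests of the fixed slope,
Benjamini–Yekutieli FDR, and cluster-extent thresholding with
Table-style cluster summaries.

**Phantom simulator.**  A 2D longitudinal phantom with four canonical
structures (background, white-matter square, ventricle square,
gray-matter rectangle), cross-sectional intensity/size variability,
rigid-shift registration errors, a population trend (ventricular
enlargement, gray/white atrophy), a subject-specific longitudinal factor
and visit noise — with full ground truth, for validating recovery.  A
second generator draws data exactly from the component model above.

**Score–covariate association** reports per-(component, covariate)
simple regressions (slope, R^2, r, p) with optional panels.

See `docs/methods.md` for the estimation details, the phantom's
generative model and calibration, and known limitations.

## Worked example

```python
import numpy as np
from lfpca import (PhantomParams, simulate_phantom, fit_lfpca,
                   variance_table, fit_voxelwise, cluster_extent)

params = PhantomParams(grid=(100, 100), seed=0)   # 50 subjects, 4 visits
stack, truth = simulate_phantom(params)

fit = fit_lfpca(stack)                 # demean -> SVD -> moments -> eigen -> scores
table = variance_table(fit)
print(table[table.process == "subject"].head(6).round(3).to_string(index=False))

k = int(np.argmax(fit.longitudinal_ratios))
r = np.corrcoef(fit.xi[:, k], truth["long_factor"])[0, 1]
print(f"longitudinal component: #{k+1}, ratio "
      f"{fit.longitudinal_ratios[k]:.2f}, score-vs-truth r = {r:+.3f}")

res = fit_voxelwise(stack, q=0.05)     # voxelwise LMM + BY-FDR
print(cluster_extent(res.reject, res.t1, stack).round(2).to_string(index=False))
```

Output:

```
process  component  eigenvalue  variance_share  longitudinal_ratio
subject          1 4662711.817           0.681               0.991
subject          2  591274.351           0.086               0.033
subject          3  495607.672           0.072               0.010
subject          4  383415.205           0.056               0.150
subject          5  203026.031           0.030               0.076
subject          6  186875.783           0.027               0.062

longitudinal component: #1, ratio 0.99, score-vs-truth r = -1.000
       sign  size  t_extreme  peak_x  peak_y  peak_z  cog_x  cog_y  cog_z
enlargement   256       5.93      49      42       0   49.5   49.5    0.0
```

Reading this: the first subject-specific component is almost purely
longitudinal (ratio 0.99) and its subject scores track the phantom's true
longitudinal factor essentially perfectly (|r| = 1.000; the sign of an
eigenvector is a convention).  The remaining components are
cross-sectional — white-matter intensity, registration shifts, structure
sizes — with ratios near 0.  The mixed-model VBM branch finds exactly one
significant cluster: a 256-voxel enlargement cluster centered on the
ventricle (centre of gravity 49.5, 49.5), while gray/white trends stay
below threshold — the complementary mass-univariate view of the same
stack.

## Command line

```sh
lfpca simulate  --grid 100 100 --subjects 50 --seed 1 --out run/sim
lfpca fit-lfpca --design run/sim/design.csv --mask run/sim/mask.nii.gz --out run/fit
lfpca fit-vbm   --design run/sim/design.csv --mask run/sim/mask.nii.gz --out run/vbm
lfpca report    --fit run/fit/lfpca_fit.npz --covariates covs.csv --out run/rep
```

Each subcommand accepts `--config config.yaml` (flags override file
values) and writes a `manifest.json` with inputs, parameters and seed.
Real data enter through `load_stack`: one NIfTI volume per subject-visit,
a binary mask, and a CSV design table (`file, subject_id, visit, time`);
optional 4 mm FWHM smoothing matches standard preprocessing.

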