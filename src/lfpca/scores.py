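"""Relating subject-specific component scores to covariates.

Per (component, covariate) pair a simple linear regression of the covariate
on the scores is fitted, reporting slope, intercept, Pearson r, R^2 and the
two-sided p-value of the slope.  Incomplete covariate rows are dropped
pairwise.  No multiple-testing correction is applied across the grid by
default (associations are reported per covariate); a Benjamini-Yekutieli
option is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import LfpcaFit, variance_table
from .errors import DataError

__all__ = ["associate", "score_report", "scores_frame"]


def scores_frame(fit: LfpcaFit) -> pd.DataFrame:
    """Subject-specific scores as a DataFrame indexed by subject id."""
    if fit.xi is None:
        raise DataError("scores have not been estimated for this fit")
    cols = [f"LFPC{k + 1}" for k in range(fit.n_x)]
    return pd.DataFrame(fit.xi, index=pd.Index(fit.subjects, name="subject_id"),
                        columns=cols)


def associate(
    scores,
    covariates: pd.DataFrame,
    *,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Simple linear regressions of each covariate on each score column.

    ``scores``: DataFrame indexed by subject id (see :func:`scores_frame`).
    Rows with a missing covariate value are dropped pairwise; fewer than 3
    complete pairs raises a :class:`~lfpca.errors.DataError` naming the
    covariate.  ``fdr=True`` flags significance on Benjamini-Yekutieli
    adjusted p-values instead of raw ones.
    """
    scores = pd.DataFrame(scores)
    covariates = pd.DataFrame(covariates)
    common = scores.index.intersection(covariates.index)
    rows = []
    for comp in scores.columns:
        for cov in covariates.columns:
            x = scores.loc[common, comp].to_numpy(dtype=float)
            y = pd.to_numeric(covariates.loc[common, cov],
                              errors="coerce").to_numpy(dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            n = int(keep.sum())
            if n < 3:
                raise DataError(
                    f"covariate {cov!r}: only {n} complete pairs (< 3)")
            xs, ys = x[keep], y[keep]
            if np.ptp(xs) == 0 or np.ptp(ys) == 0:
                slope = intercept = r = np.nan
                pval = 1.0
            else:
                res = stats.linregress(xs, ys)
                slope, intercept = res.slope, res.intercept
                r, pval = res.rvalue, res.pvalue
            rows.append({
                "component": comp, "covariate": cov, "n": n,
                "slope": slope, "intercept": intercept,
                "r": r, "r2": r ** 2 if np.isfinite(r) else np.nan,
                "pvalue": pval,
            })
    table = pd.DataFrame(rows)
    if len(table):
        if fdr:
            from .vbm import by_fdr
            adj, rej = by_fdr(table["pvalue"].to_numpy(), alpha)
            table["pvalue_adj"] = adj
            table["significant"] = rej
        else:
            table["significant"] = table["pvalue"] < alpha
    return table


def score_report(
    fit: LfpcaFit,
    covariates: pd.DataFrame | None = None,
    *,
    alpha: float = 0.05,
    outdir=None,
    make_plots: bool = False,
) -> dict:
    """Variance table, longitudinal ratios and (optionally) associations.

    Returns a dict with keys ``variance`` and ``associations`` (None when
    no covariates are supplied).  With ``make_plots`` and ``outdir`` set,
    renders a variance bar panel and association scatter panels as PNG.
    """
    var = variance_table(fit)
    assoc = None
    if covariates is not None and fit.n_x > 0:
        assoc = associate(scores_frame(fit), covariates, alpha=alpha)
    report = {"variance": var, "associations": assoc}
    if outdir is not None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        var.to_csv(outdir / "variance_table.csv", index=False)
        if assoc is not None:
            assoc.to_csv(outdir / "associations.csv", index=False)
        if make_plots:
            _render_panels(fit, var, covariates, outdir)
    return report


def _render_panels(fit, var, covariates, outdir) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = var[var["process"] == "subject"]
    if len(sub):
        fig, ax = plt.subplots(figsize=(6, 4))
        share = sub["variance_share"].to_numpy()
        ratio = sub["longitudinal_ratio"].to_numpy()
        x = sub["component"].to_numpy()
        ax.bar(x, share * (1 - ratio), color="lightgray",
               label="baseline part")
        ax.bar(x, share * ratio, bottom=share * (1 - ratio),
               color="dimgray", label="longitudinal part")
        ax.set_xlabel("subject-specific component")
        ax.set_ylabel("share of total variance")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "variance_components.png", dpi=120)
        plt.close(fig)
    if covariates is not None and fit.xi is not None and fit.n_x > 0:
        sf = scores_frame(fit)
        covariates = pd.DataFrame(covariates)
        ncomp, ncov = len(sf.columns), len(covariates.columns)
        fig, axes = plt.subplots(ncomp, ncov,
                                 figsize=(2.5 * ncov, 2.5 * ncomp),
                                 squeeze=False)
        common = sf.index.intersection(covariates.index)
        for a, comp in enumerate(sf.columns):
            for b, cov in enumerate(covariates.columns):
                ax = axes[a][b]
                ax.scatter(sf.loc[common, comp],
                           covariates.loc[common, cov], s=8)
                if a == 0:
                    ax.set_title(str(cov), fontsize=8)
                if b == 0:
                    ax.set_ylabel(comp, fontsize=8)
                ax.tick_params(labelsize=6)
        fig.tight_layout()
        fig.savefig(outdir / "score_covariate_panels.png", dpi=120)
        plt.close(fig)
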