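"""Per-gene Poisson mixed-model differential expression.

The workflow mirrors the count-based testing pipeline for the soybean
root-hair heat-stress design: drop genes with fewer than 10 total reads, fit
each remaining gene a Poisson log-linear mixed model (library-size offset,
treatment fixed effect, replicate and plate random intercepts) separately
for each (tissue, time) heat-vs-control contrast, test the treatment term by
likelihood ratio against chi-square(1), convert p-values to Storey q-values
per contrast, and call genes differentially expressed at q <= 0.01 with at
least a twofold model-based change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .glmm import GlmmFit, fit_poisson_glmm, group_codes, lrt_test
from .qvalue import storey_qvalues

__all__ = [
    "filter_low_counts",
    "compute_rpkm",
    "fit_gene_glmm",
    "call_de",
    "run_de",
    "PoissonMixedDE",
]

REQUIRED_DESIGN_COLUMNS = ("sample", "tissue", "treatment", "time_h", "replicate", "plate", "libsize")


def filter_low_counts(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Drop genes whose summed count across all samples is below ``min_total``.

    A gene with row total exactly ``min_total`` is kept.  Gene order is
    preserved.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValueError("count matrix is empty")
    return counts.loc[counts.sum(axis=1) >= min_total]


def compute_rpkm(count: float, gene_length_bp: float, libsize: float) -> float:
    """Reads per kilobase per million mapped reads: count * 1e9 / (libsize * length)."""
    if gene_length_bp <= 0 or libsize <= 0:
        raise ValueError("gene length and library size must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count * 1e9 / (libsize * gene_length_bp)


def _design_arrays(design: pd.DataFrame):
    heat = design["treatment"].str.startswith("heat").to_numpy().astype(float)
    offset = np.log(design["libsize"].to_numpy(float))
    factors = [group_codes(design["replicate"]), group_codes(design["plate"])]
    return heat, offset, factors


def fit_gene_glmm(y, design: pd.DataFrame, include_treatment: bool = True) -> GlmmFit:
    """Fit the per-gene Poisson mixed model for one contrast's samples.

    ``design`` needs treatment, replicate, plate and libsize columns; the
    offset is log(libsize).  With ``include_treatment=False`` the nested
    null model (intercept plus random effects only) is fitted, for use as
    the reduced model of the likelihood-ratio test.
    """
    y = np.asarray(y, float)
    heat, offset, factors = _design_arrays(design)
    if include_treatment:
        for grp in (0.0, 1.0):
            if int(np.sum(heat == grp)) < 2:
                raise ValueError("need >= 2 samples per treatment group")
        X = np.column_stack([np.ones_like(heat), heat])
    else:
        X = np.ones((len(heat), 1))
    beta, sigmas, ll, conv = fit_poisson_glmm(y, X, offset, factors)
    return GlmmFit(
        beta0=float(beta[0]),
        beta_trt=float(beta[1]) if include_treatment else 0.0,
        sigma2_rep=float(sigmas[0] ** 2),
        sigma2_plate=float(sigmas[1] ** 2),
        loglik=float(ll),
        converged=bool(conv),
        has_treatment=include_treatment,
        n_obs=len(y),
    )


def call_de(results: pd.DataFrame, q_threshold: float = 0.01, min_fold: float = 2.0) -> pd.DataFrame:
    """Apply the FDR + fold-change calling rule and set the direction flag.

    A gene is called when q <= ``q_threshold`` and |log2 fold change| >=
    log2(``min_fold``); direction is "up"/"down" by the sign of the fold
    change, "none" for uncalled genes.
    """
    if "q" not in results.columns:
        raise ValueError("results must carry q-values; run storey_qvalues first")
    out = results.copy()
    lfc_cut = np.log2(min_fold)
    out["called"] = (out["q"] <= q_threshold) & (out["log2_fc"].abs() >= lfc_cut)
    out["direction"] = np.where(
        ~out["called"], "none", np.where(out["log2_fc"] > 0, "up", "down")
    )
    return out


def run_de(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    min_total: int = 10,
    q_threshold: float = 0.01,
    min_fold: float = 2.0,
    pi0: float | None = None,
) -> pd.DataFrame:
    """Full DE chain over every (tissue, time) contrast in the design.

    Returns one row per gene per contrast with columns gene, tissue, time_h,
    lrt_stat, p, q, log2_fc, called, direction.  q-values are computed per
    contrast (each contrast is its own family of tests).
    """
    missing = [c for c in REQUIRED_DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"sample sheet is missing columns: {', '.join(missing)}")
    if not set(design["sample"]) <= set(counts.columns):
        raise ValueError("sample sheet references samples absent from the count matrix")
    kept = filter_low_counts(counts, min_total=min_total)

    frames = []
    for (tissue, time_h), sub in design.groupby(["tissue", "time_h"], sort=True):
        if sub["treatment"].nunique() < 2:
            continue
        sub = sub.reset_index(drop=True)
        mat = kept[sub["sample"].tolist()].to_numpy(float)
        heat, offset, factors = _design_arrays(sub)
        if min(np.sum(heat == 0), np.sum(heat == 1)) < 2:
            raise ValueError(
                f"contrast ({tissue}, {time_h}) needs >= 2 samples per treatment group"
            )
        X_full = np.column_stack([np.ones_like(heat), heat])
        X_red = np.ones((len(heat), 1))
        stats = np.empty(len(kept))
        pvals = np.empty(len(kept))
        lfc = np.empty(len(kept))
        ln2 = np.log(2.0)
        for i in range(len(kept)):
            y = mat[i]
            beta, _, ll_full, _ = fit_poisson_glmm(y, X_full, offset, factors)
            _, _, ll_red, _ = fit_poisson_glmm(y, X_red, offset, factors)
            stat = max(0.0, 2.0 * (ll_full - ll_red))
            stats[i] = stat
            pvals[i] = float(chi2.sf(stat, df=1))
            lfc[i] = beta[1] / ln2
        res = pd.DataFrame(
            {
                "gene": kept.index,
                "tissue": tissue,
                "time_h": time_h,
                "lrt_stat": stats,
                "p": pvals,
                "q": storey_qvalues(pvals, pi0=pi0),
                "log2_fc": lfc,
            }
        )
        frames.append(call_de(res, q_threshold=q_threshold, min_fold=min_fold))
    if not frames:
        raise ValueError("design contains no contrast with both treatments")
    return pd.concat(frames, ignore_index=True)


class PoissonMixedDE(BaseEstimator):
    """Poisson mixed-model differential-expression tester, estimator-style.

    Parameters
    ----------
    min_total : low-count filter threshold on per-gene row totals.
    q_threshold : Storey q-value cutoff for calling (FDR level).
    min_fold : minimum fold change (linear scale) for calling.
    pi0 : fix the null proportion instead of estimating it (None = estimate).

    Attributes (after fit)
    ----------------------
    results_ : DataFrame with one row per gene x contrast.
    n_genes_tested_ : genes surviving the low-count filter.
    """

    def __init__(self, min_total: int = 10, q_threshold: float = 0.01,
                 min_fold: float = 2.0, pi0: float | None = None):
        self.min_total = min_total
        self.q_threshold = q_threshold
        self.min_fold = min_fold
        self.pi0 = pi0

    def fit(self, X: pd.DataFrame, y=None, *, design: pd.DataFrame):
        """Run the DE chain on a gene x sample count matrix with its sample sheet."""
        self.results_ = run_de(
            X,
            design,
            min_total=self.min_total,
            q_threshold=self.q_threshold,
            min_fold=self.min_fold,
            pi0=self.pi0,
        )
        self.n_genes_tested_ = int(self.results_["gene"].nunique())
        return self

    def called(self) -> pd.DataFrame:
        """Rows of ``results_`` that pass the calling rule."""
        if not hasattr(self, "results_"):
            raise AttributeError("fit the estimator first")
        return self.results_[self.results_["called"]]
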