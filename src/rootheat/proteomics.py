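"""iTRAQ 8-plex reporter-ion quantification, peptide to protein.

The chain: split each MS/MS scan's base-peak intensity over the eight
reporter channels by their intensity fractions, sum multiple scans of a
peptide into one per-channel value and log2-transform, bridge plexes on the
mean of the two pooled-reference channels, remove residual channel bias by
central-tendency (median) normalization, roll peptides up to proteins with
Rrollup (scale every peptide to the most present / most abundant one, take
the per-sample median), and test 40 degC against 25 degC per time point by
one-way ANOVA with Benjamini-Hochberg correction and a twofold cutoff.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

__all__ = [
    "channel_intensities_from_scan",
    "consolidate_peptides",
    "normalize_peptides",
    "rrollup_protein",
    "rollup_proteins",
    "protein_de_test",
    "ITraqQuantifier",
]

CHANNEL_COLS = [f"ch{c}" for c in range(1, 9)]


def channel_intensities_from_scan(reporters, base_peak: float) -> np.ndarray:
    """Per-channel intensities of one scan: base_peak x reporter fraction.

    Fractions are reporter intensities over their sum, so the returned
    channel intensities always sum to the base peak.
    """
    rep = np.asarray(reporters, float)
    if rep.shape != (8,):
        raise ValueError("expected 8 reporter intensities")
    if np.any(rep < 0) or base_peak <= 0:
        raise ValueError("reporter intensities must be >= 0 and base peak > 0")
    total = rep.sum()
    if total == 0:
        raise ValueError("all reporter intensities are zero")
    return base_peak * rep / total


def consolidate_peptides(spectra: pd.DataFrame) -> pd.DataFrame:
    """Scan-level report -> peptide x channel log2 abundances per plex.

    Channel intensities of all scans of a (peptide, plex) are summed, then
    log2-transformed; channels that remain zero become missing (NaN), never
    -inf.  Scans whose reporters are all zero are skipped with a warning.
    """
    required = {"scan", "peptide", "protein", "plex", "base_peak", *CHANNEL_COLS}
    missing = required - set(spectra.columns)
    if missing:
        raise ValueError(f"spectrum report is missing columns: {sorted(missing)}")
    rep = spectra[CHANNEL_COLS].to_numpy(float)
    totals = rep.sum(axis=1)
    bad = totals <= 0
    if bad.any():
        warnings.warn(f"skipping {int(bad.sum())} scans with all-zero reporters")
    ok = spectra.loc[~bad].copy()
    rep = ok[CHANNEL_COLS].to_numpy(float)
    inten = rep / rep.sum(axis=1, keepdims=True) * ok["base_peak"].to_numpy(float)[:, None]
    ok[CHANNEL_COLS] = inten
    summed = ok.groupby(["protein", "peptide", "plex"], sort=True)[CHANNEL_COLS].sum()
    with np.errstate(divide="ignore"):
        log2 = np.log2(summed.to_numpy())
    log2[~np.isfinite(log2)] = np.nan
    out = pd.DataFrame(log2, index=summed.index, columns=CHANNEL_COLS).reset_index()
    return out


def normalize_peptides(
    peptides: pd.DataFrame, ref_channels: tuple = (4, 8)
) -> pd.DataFrame:
    """Pooled-reference bridging then central-tendency normalization.

    Step 1 subtracts, per peptide row, the mean of its two pooled-reference
    channels, putting all plexes on a common relative scale.  Step 2 shifts
    each (plex, channel) column so its median equals the global median of
    all normalized values, removing channel bias.  Peptides whose reference
    channels are both missing cannot be bridged and are dropped (counted in
    a warning).
    """
    ref_cols = [f"ch{c}" for c in ref_channels]
    for col in ref_cols:
        if col not in peptides.columns:
            raise ValueError(f"reference channel column {col} missing")
    out = peptides.copy()
    ref_mean = out[ref_cols].mean(axis=1, skipna=True)
    dropped = ref_mean.isna()
    if dropped.any():
        warnings.warn(
            f"dropping {int(dropped.sum())} peptide rows with no pooled-reference signal"
        )
        out = out.loc[~dropped]
        ref_mean = ref_mean.loc[~dropped]
    out[CHANNEL_COLS] = out[CHANNEL_COLS].sub(ref_mean, axis=0)

    global_median = np.nanmedian(out[CHANNEL_COLS].to_numpy())
    for plex, idx in out.groupby("plex").groups.items():
        block = out.loc[idx, CHANNEL_COLS]
        shift = block.median(skipna=True) - global_median
        out.loc[idx, CHANNEL_COLS] = block.sub(shift, axis=1)
    return out


def rrollup_protein(peptide_rows: pd.DataFrame, sample_cols=None) -> pd.Series:
    """Rrollup one protein's peptide x sample log2 table to a protein profile.

    The reference peptide is the one with the most present values, ties
    broken by highest median abundance, then input order.  Every other
    peptide is shifted by the median difference to the reference over their
    shared samples; the protein value per sample is the median of the
    shifted peptide values present there.  Peptides sharing no samples with
    the reference are excluded.
    """
    if len(peptide_rows) == 0:
        raise ValueError("protein has no peptides")
    cols = list(sample_cols) if sample_cols is not None else CHANNEL_COLS
    mat = peptide_rows[cols].to_numpy(float)
    presence = np.sum(~np.isnan(mat), axis=1)
    medians = np.array([np.nanmedian(r) if np.any(~np.isnan(r)) else -np.inf for r in mat])
    ref = max(range(len(mat)), key=lambda i: (presence[i], medians[i], -i))
    ref_row = mat[ref]
    shifted = []
    for i, row in enumerate(mat):
        shared = ~np.isnan(row) & ~np.isnan(ref_row)
        if not shared.any():
            warnings.warn("excluding a peptide sharing no samples with the reference")
            continue
        offset = np.nanmedian(ref_row[shared] - row[shared])
        shifted.append(row + offset)
    shifted = np.vstack(shifted)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN sample slices
        prot = np.nanmedian(shifted, axis=0)
    return pd.Series(prot, index=cols)


def rollup_proteins(peptides: pd.DataFrame, sample_cols=None) -> pd.DataFrame:
    """Apply Rrollup per (protein, plex); returns protein x channel log2 table."""
    cols = list(sample_cols) if sample_cols is not None else CHANNEL_COLS
    rows = {}
    for (protein, plex), grp in peptides.groupby(["protein", "plex"], sort=True):
        rows[(protein, plex)] = rrollup_protein(grp, sample_cols=cols)
    out = pd.DataFrame(rows).T
    out.index.names = ["protein", "plex"]
    return out


def protein_de_test(
    protein_abund: pd.DataFrame,
    channel_design: pd.DataFrame,
    alpha: float = 0.05,
    min_fold: float = 2.0,
    min_per_group: int = 2,
    global_correction: bool = False,
) -> pd.DataFrame:
    """Per-time-point ANOVA of 40 degC vs 25 degC protein abundances.

    ``protein_abund`` is the rollup output indexed by (protein, plex);
    ``channel_design`` maps (plex, channel) to treatment/time/replicate.
    Benjamini-Hochberg is applied across proteins within each time point
    (or globally when ``global_correction``).  log2 fold change is
    mean(40 degC) - mean(25 degC); a protein is called at adjusted p <
    ``alpha`` and |log2_fc| >= log2(``min_fold``).  Proteins with fewer than
    ``min_per_group`` values in either group are reported untestable.
    """
    results = []
    design = channel_design[channel_design["treatment"] != "pooled_ref"]
    # wide layout: rows = proteins, columns = (plex, channel) samples
    wide = protein_abund.unstack(level="plex")
    wide.columns = [(plex, ch) for ch, plex in wide.columns]  # (plex, "chN") keys
    for time_h, tsub in design.groupby("time_h", sort=True):
        ctrl_cols = [(r["plex"], f"ch{int(r['channel'])}")
                     for _, r in tsub.iterrows() if r["treatment"].startswith("control")]
        heat_cols = [(r["plex"], f"ch{int(r['channel'])}")
                     for _, r in tsub.iterrows() if r["treatment"].startswith("heat")]
        ctrl_mat = wide[[c for c in ctrl_cols if c in wide.columns]].to_numpy(float)
        heat_mat = wide[[c for c in heat_cols if c in wide.columns]].to_numpy(float)
        for pi, protein in enumerate(wide.index):
            ctrl = ctrl_mat[pi][~np.isnan(ctrl_mat[pi])]
            heat = heat_mat[pi][~np.isnan(heat_mat[pi])]
            if len(ctrl) < min_per_group or len(heat) < min_per_group:
                results.append({"protein": protein, "time_h": time_h, "p": np.nan,
                                "log2_fc": np.nan, "testable": False})
                continue
            if np.allclose(ctrl, ctrl[0]) and np.allclose(heat, heat[0]) and np.isclose(ctrl[0], heat[0]):
                f_p = 1.0
            else:
                f_p = float(stats.f_oneway(ctrl, heat).pvalue)
                if np.isnan(f_p):
                    f_p = 1.0
            results.append({
                "protein": protein,
                "time_h": time_h,
                "p": f_p,
                "log2_fc": float(heat.mean() - ctrl.mean()),
                "testable": True,
            })
    res = pd.DataFrame(results)
    res["p_adj"] = np.nan
    if global_correction:
        groups = [res.index[res["testable"]]]
    else:
        groups = [
            res.index[(res["time_h"] == t) & res["testable"]]
            for t in res["time_h"].unique()
        ]
    for idx in groups:
        if len(idx):
            res.loc[idx, "p_adj"] = multipletests(res.loc[idx, "p"], method="fdr_bh")[1]
    res["called"] = (
        res["testable"]
        & (res["p_adj"] < alpha)
        & (res["log2_fc"].abs() >= np.log2(min_fold))
    )
    return res


class ITraqQuantifier(BaseEstimator, TransformerMixin):
    """Spectrum report -> protein abundance transformer with DE testing.

    Parameters
    ----------
    ref_channels : the two pooled-reference channels (1-based), default (4, 8).
    alpha, min_fold : calling thresholds for the per-time-point ANOVA.
    global_correction : apply BH across all time points at once instead of
        within each time point.

    Attributes (after fit/transform)
    --------------------------------
    peptides_ : normalized peptide x channel log2 abundances.
    proteins_ : Rrollup protein x channel abundances, indexed (protein, plex).
    """

    def __init__(self, ref_channels: tuple = (4, 8), alpha: float = 0.05,
                 min_fold: float = 2.0, global_correction: bool = False):
        self.ref_channels = ref_channels
        self.alpha = alpha
        self.min_fold = min_fold
        self.global_correction = global_correction

    def fit(self, X: pd.DataFrame, y=None):
        consolidated = consolidate_peptides(X)
        self.peptides_ = normalize_peptides(consolidated, ref_channels=self.ref_channels)
        self.proteins_ = rollup_proteins(self.peptides_)
        return self

    def transform(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        """Return the protein x channel abundance table from :meth:`fit`."""
        if not hasattr(self, "proteins_"):
            raise AttributeError("fit the transformer first")
        return self.proteins_

    def test(self, channel_design: pd.DataFrame) -> pd.DataFrame:
        """Run the per-time-point differential test on the fitted proteins."""
        return protein_de_test(
            self.proteins_, channel_design, alpha=self.alpha,
            min_fold=self.min_fold, global_correction=self.global_correction,
        )
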