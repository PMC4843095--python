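"""Cross-omics integration: set algebra, correlation, qPCR, enrichment.

These are the analyses that sit on top of the gene- and protein-level
results: directional overlap partitions between tissues, the core of genes
responding at every time point, Pearson correlation between protein and
mRNA log2 fold changes, qPCR fold changes from delta-Ct values, and
hypergeometric term-enrichment testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .qvalue import storey_qvalues

__all__ = [
    "DirectionalSet",
    "overlap_partition",
    "timepoint_core",
    "mrna_protein_correlation",
    "qpcr_fold_change",
    "enrichment_test",
]


@dataclass
class DirectionalSet:
    """Up- and down-regulated gene id sets for one (tissue, time) label."""

    label: str
    up: set = field(default_factory=set)
    down: set = field(default_factory=set)

    def __post_init__(self):
        self.up = set(self.up)
        self.down = set(self.down)
        if self.up & self.down:
            raise ValueError("a gene cannot be both up and down in one set")

    @property
    def total(self) -> set:
        return self.up | self.down

    @classmethod
    def from_results(cls, results: pd.DataFrame, label: str) -> "DirectionalSet":
        """Build from a called-DE results frame (gene, direction columns)."""
        called = results[results["called"]] if "called" in results.columns else results
        return cls(
            label=label,
            up=set(called.loc[called["direction"] == "up", "gene"]),
            down=set(called.loc[called["direction"] == "down", "gene"]),
        )


def overlap_partition(a: DirectionalSet, b: DirectionalSet) -> dict:
    """Directional common/unique partition of two DE sets.

    Genes concordant in direction are counted as common; genes called in
    both sets but with opposite directions go to a separate ``discordant``
    list and count in neither common set.  Per direction,
    |unique_a| + |common| = |a|.
    """
    discordant = (a.up & b.down) | (a.down & b.up)
    common_up = (a.up & b.up)
    common_down = (a.down & b.down)
    out = {
        "common_up": common_up,
        "common_down": common_down,
        "unique_a_up": a.up - common_up,
        "unique_a_down": a.down - common_down,
        "unique_b_up": b.up - common_up,
        "unique_b_down": b.down - common_down,
        "discordant": discordant,
    }
    out["counts"] = {k: len(v) for k, v in out.items() if isinstance(v, set)}
    return out


def timepoint_core(sets: list[DirectionalSet], denominator: str = "union") -> dict:
    """Direction-consistent intersection across time points for one tissue.

    ``core`` holds genes up at every time point plus genes down at every
    time point; ``union`` holds genes called at any time point.  The
    reported fraction is |core| over |union| by default, or over the mean
    per-time-point set size with ``denominator="mean_per_timepoint"``.
    """
    if len(sets) < 2:
        raise ValueError("need at least two time points")
    core_up = set.intersection(*[s.up for s in sets])
    core_down = set.intersection(*[s.down for s in sets])
    union = set.union(*[s.total for s in sets])
    core = core_up | core_down
    if denominator == "union":
        denom = len(union)
    elif denominator == "mean_per_timepoint":
        denom = float(np.mean([len(s.total) for s in sets]))
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    fraction = len(core) / denom if denom else 0.0
    return {
        "core": core,
        "core_up": core_up,
        "core_down": core_down,
        "union": union,
        "fraction": fraction,
    }


def mrna_protein_correlation(
    protein_log2fc: pd.Series, mrna_log2fc: pd.Series
) -> dict:
    """Pearson correlation of protein vs mRNA log2 fold changes on matched ids.

    Also reports the matched fraction (matched ids over proteins).  Fewer
    than three matched pairs leaves the correlation undefined (NaN, flagged).
    """
    matched = protein_log2fc.index.intersection(mrna_log2fc.index)
    n_matched = len(matched)
    frac = n_matched / len(protein_log2fc) if len(protein_log2fc) else 0.0
    if n_matched < 3:
        warnings.warn("fewer than 3 matched mRNA-protein pairs; correlation undefined")
        return {"r": float("nan"), "n_matched": n_matched, "matched_fraction": frac,
                "defined": False}
    r = float(stats.pearsonr(protein_log2fc.loc[matched], mrna_log2fc.loc[matched])[0])
    return {"r": r, "n_matched": n_matched, "matched_fraction": frac, "defined": True}


def qpcr_fold_change(delta_ct_heat: float, delta_ct_ctrl: float, peff: float) -> float:
    """Heat/control expression ratio from delta-Ct values: Peff^(dCt_ctrl - dCt_heat).

    Expression is E = Peff^(-dCt) with dCt = Ct_gene - Ct_cons6, so the fold
    change is the ratio of the two expressions.
    """
    if not 1.0 < peff <= 2.0:
        raise ValueError("primer efficiency Peff must be in (1, 2]")
    return float(peff ** (delta_ct_ctrl - delta_ct_heat))


def qpcr_fold_change_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-time-point fold changes from a qPCR record table.

    Replicate delta-Ct values are averaged within (gene, time, treatment)
    before the ratio is formed.
    """
    need = {"gene_id", "Peff", "treatment", "time_h", "delta_ct"}
    missing = need - set(records.columns)
    if missing:
        raise ValueError(f"qPCR table is missing columns: {sorted(missing)}")
    rows = []
    for (gene, t), grp in records.groupby(["gene_id", "time_h"], sort=True):
        peff = float(grp["Peff"].iloc[0])
        ctrl = grp.loc[grp["treatment"].str.startswith("control"), "delta_ct"].mean()
        heat = grp.loc[grp["treatment"].str.startswith("heat"), "delta_ct"].mean()
        if np.isnan(ctrl) or np.isnan(heat):
            continue
        rows.append({"gene_id": gene, "time_h": t,
                     "fold_change": qpcr_fold_change(heat, ctrl, peff)})
    return pd.DataFrame(rows)


def enrichment_test(
    study_set,
    category_map: dict,
    background_set,
    fdr: float = 0.05,
    pi0: float | None = 1.0,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of terms in a study gene set.

    ``category_map`` maps term -> set of member genes.  For each non-empty
    term the upper-tail probability P(X >= overlap) of the hypergeometric
    draw (|study| from |background| with |term| successes) is computed;
    q-values across terms (Benjamini-Hochberg by default, pi0-estimating
    when ``pi0=None``) flag enrichment at q <= ``fdr``.
    """
    study = set(study_set)
    background = set(background_set)
    if not study <= background:
        raise ValueError("study genes must all appear in the background")
    rows = []
    for term, members in category_map.items():
        members = set(members) & background
        if not members:
            warnings.warn(f"term {term!r} has no background genes; skipped")
            continue
        k = len(study & members)
        p = float(stats.hypergeom.sf(k - 1, len(background), len(members), len(study)))
        rows.append({"term": term, "n_study_hits": k, "term_size": len(members),
                     "p": min(p, 1.0)})
    if not rows:
        return pd.DataFrame(columns=["term", "n_study_hits", "term_size", "p", "q", "enriched"])
    out = pd.DataFrame(rows)
    out["q"] = storey_qvalues(out["p"].to_numpy(), pi0=pi0)
    out["enriched"] = out["q"] <= fdr
    return out
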