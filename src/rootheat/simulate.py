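"""Synthetic data generators with planted ground truth.

Every downstream stage of the pipeline (count-based differential expression,
module-network inference, iTRAQ protein quantification, qPCR fold changes) is
exercised on data generated here, so each generator emits both the tables a
real experiment would produce and a :class:`SimTruth` record of what was
planted.  Defaults emulate the study design the pipeline targets: two root
tissues (root hairs RH and stripped roots STR), a 25 degC control versus a
40 degC heat treatment, time points 0/3/6/12/24 h, two biological replicates
and plate-level batching, with 8-plex iTRAQ runs carrying two pooled
reference channels.

All randomness flows through ``numpy.random.default_rng(seed)``; equal seeds
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimTruth",
    "gen_rnaseq_counts",
    "gen_module_expression",
    "gen_itraq_peptides",
    "gen_qpcr",
]

CONTROL = "control_25C"
HEAT = "heat_40C"


class ConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Knobs for all generators; see module docstring for the defaults' logic.

    ``effect_log_fc`` is the natural-log treatment effect planted in true DE
    genes (ln 2 = a twofold change).  ``sigma_rep`` / ``sigma_plate`` are the
    standard deviations of the replicate and plate random intercepts on the
    log-mean scale.  ``leaf_sep`` is the spacing between the expression
    regimes at the leaves of planted regulator trees, and ``noise_sd`` the
    within-leaf spread, both on the log2-fold-change scale of the module
    expression matrix.
    """

    n_genes: int = 2000
    n_tf: int = 6
    tissues: tuple = ("RH", "STR")
    timepoints: tuple = (0, 3, 6, 12, 24)
    n_replicates: int = 2
    n_plates: int = 2
    libsize_range: tuple = (8e5, 1.2e6)
    de_fraction: float = 0.10
    effect_log_fc: float = float(np.log(2.0))
    sigma_rep: float = 0.1
    sigma_plate: float = 0.1
    n_modules: int = 2
    tree_depth: int = 1
    leaf_sep: float = 4.0
    noise_sd: float = 0.1
    n_proteins: int = 500
    peptides_per_protein: tuple = (2, 4)
    n_channels: int = 8
    ref_channels: tuple = (4, 8)
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "n_tf", "n_replicates", "n_plates", "n_modules", "n_proteins"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("de_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.n_channels != 8:
            raise ConfigError("iTRAQ generator models 8-plex runs only")
        r1, r2 = self.ref_channels
        if r1 == r2 or not (1 <= r1 <= 8 and 1 <= r2 <= 8):
            raise ConfigError("ref_channels must be two distinct channels in 1..8")
        lo, hi = self.libsize_range
        if lo <= 0 or hi < lo:
            raise ConfigError("libsize_range must be a positive (lo, hi) pair")
        plo, phi = self.peptides_per_protein
        if plo < 1 or phi < plo:
            raise ConfigError("peptides_per_protein range is empty")
        if self.tree_depth < 0:
            raise ConfigError("tree_depth must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.sigma_rep < 0 or self.sigma_plate < 0:
            raise ConfigError("random-effect SDs must be >= 0")


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside every generated table."""

    de_genes: dict = field(default_factory=dict)  # gene -> signed ln fold change
    module_assignment: dict = field(default_factory=dict)  # gene -> module index
    regulator_trees: list = field(default_factory=list)  # planted tree dicts
    protein_effects: dict = field(default_factory=dict)  # protein -> {time_h: log2 shift}

    def to_dict(self):
        return asdict(self)


def gen_rnaseq_counts(config: SimConfig):
    """Simulate a gene x sample raw-count matrix plus design sheet and truth.

    Counts are Poisson with log-mean = log(libsize) + gene baseline
    (+ treatment effect for true DE genes in heat samples)
    + replicate effect ~ N(0, sigma_rep^2) + plate effect ~ N(0, sigma_plate^2),
    random effects drawn independently per gene x replicate and gene x plate.
    Plates are laid out in a Latin square over (treatment, replicate) so the
    plate factor is not aliased with either.

    Returns ``(counts, design, truth)``: counts a DataFrame (genes x samples),
    design a DataFrame with one row per sample, truth a :class:`SimTruth`.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"Gene{i:05d}" for i in range(config.n_genes)]

    rows = []
    for tissue in config.tissues:
        for t in config.timepoints:
            for ti, trt in enumerate((CONTROL, HEAT)):
                for r in range(config.n_replicates):
                    plate = (ti + r) % config.n_plates
                    rows.append(
                        {
                            "sample": f"{tissue}_{trt}_{t}h_r{r + 1}",
                            "tissue": tissue,
                            "treatment": trt,
                            "time_h": t,
                            "replicate": f"r{r + 1}",
                            "plate": f"p{plate + 1}",
                        }
                    )
    design = pd.DataFrame(rows)
    design["libsize"] = rng.uniform(*config.libsize_range, size=len(design)).round().astype(int)

    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    truth = SimTruth(
        de_genes={genes[i]: float(s * config.effect_log_fc) for i, s in zip(de_idx, signs)}
    )
    effect = np.zeros(config.n_genes)
    effect[de_idx] = signs * config.effect_log_fc

    mean_lib = float(np.mean(config.libsize_range))
    baseline = rng.normal(np.log(60.0 / mean_lib), 1.0, size=config.n_genes)
    rep_eff = rng.normal(0.0, config.sigma_rep, size=(config.n_genes, config.n_replicates))
    plate_eff = rng.normal(0.0, config.sigma_plate, size=(config.n_genes, config.n_plates))

    rep_codes = design["replicate"].str.slice(1).astype(int).to_numpy() - 1
    plate_codes = design["plate"].str.slice(1).astype(int).to_numpy() - 1
    heat = (design["treatment"] == HEAT).to_numpy().astype(float)

    log_mu = (
        np.log(design["libsize"].to_numpy(float))[None, :]
        + baseline[:, None]
        + effect[:, None] * heat[None, :]
        + rep_eff[:, rep_codes]
        + plate_eff[:, plate_codes]
    )
    counts = rng.poisson(np.exp(log_mu))
    counts = pd.DataFrame(counts, index=genes, columns=design["sample"].tolist())
    return counts, design, truth


def _plant_tree(rng, tf_pool, depth, leaf_sep, n_conditions, max_tries=200):
    """Plant one regulator tree plus TF state profiles over the conditions.

    Retries the TF state draw until every leaf holds at least two conditions,
    so the planted structure is recoverable in principle.
    """
    n_tf = len(tf_pool)
    for _ in range(max_tries):
        states = rng.choice([-1, 0, 1], size=(n_tf, n_conditions), p=[0.3, 0.4, 0.3])
        tree, ok = _build_planted(rng, tf_pool, states, depth, np.arange(n_conditions))
        if ok:
            _assign_leaf_mus(rng, tree, leaf_sep)
            return tree, states
    raise ConfigError("could not plant a tree with non-degenerate leaves")


def _assign_leaf_mus(rng, tree, leaf_sep):
    """Leaf regimes spaced by leaf_sep, offset randomly so modules can differ
    even when a tree degenerates to a single leaf."""
    leaves = _collect_leaves(tree)
    n_leaves = len(leaves)
    base = int(rng.integers(-2, 3))
    mus = leaf_sep * (base + rng.permutation(n_leaves) - (n_leaves - 1) / 2.0)
    for leaf, mu in zip(leaves, mus):
        leaf["mu"] = float(mu)


def _build_planted(rng, tf_pool, states, depth, cond_idx):
    if depth == 0 or len(cond_idx) < 4:
        if len(cond_idx) < 2:
            return None, False
        return {"leaf": True, "conditions": cond_idx.tolist()}, True
    order = rng.permutation(len(tf_pool))
    for ti in order:
        for query, val in (("is_up", 1), ("is_down", -1)):
            mask = states[ti, cond_idx] == val
            if mask.sum() >= 2 and (~mask).sum() >= 2:
                yes, okl = _build_planted(rng, tf_pool, states, depth - 1, cond_idx[mask])
                no, okr = _build_planted(rng, tf_pool, states, depth - 1, cond_idx[~mask])
                if okl and okr:
                    return {
                        "leaf": False,
                        "tf": tf_pool[ti],
                        "query": query,
                        "yes": yes,
                        "no": no,
                    }, True
    return None, False


def _collect_leaves(node):
    if node["leaf"]:
        return [node]
    return _collect_leaves(node["yes"]) + _collect_leaves(node["no"])


def gen_module_expression(config: SimConfig):
    """Simulate a log2-fold-change matrix with planted regulator-tree modules.

    Conditions are the tissue x time heat-vs-control contrasts.  Each module
    gets its own regulator tree whose leaves partition the conditions; member
    genes take the leaf mean plus N(0, noise_sd^2) noise.  TF expression
    profiles are generated so they discretize cleanly to the planted
    up/normal/down states (values near +/-5 or 0 against +/-3 cutoffs).

    Returns ``(expr, regs, truth)`` where ``expr`` is genes x conditions,
    ``regs`` a dict with the TF expression matrix (``expression``) and its
    true discrete states (``states``).
    """
    if config.n_modules > config.n_genes:
        raise ConfigError("more modules than genes")
    rng = np.random.default_rng(config.seed)
    conditions = [f"{ts}_{t}h" for ts in config.tissues for t in config.timepoints]
    n_cond = len(conditions)
    tf_ids = [f"TF{i + 1:02d}" for i in range(config.n_tf)]
    genes = [f"ModGene{i:04d}" for i in range(config.n_genes)]

    # one consistent TF state profile; every module's tree is planted against
    # it, and module mean profiles are kept mutually distinct so planted
    # modules are identifiable
    first_tree, states = _plant_tree(rng, tf_ids, config.tree_depth, config.leaf_sep, n_cond)
    trees = [first_tree]
    profiles = [_leaf_lookup(first_tree, n_cond)]
    for _ in range(1, config.n_modules):
        for _try in range(200):
            tree, _ = _replant_against(rng, tf_ids, states, config)
            prof = _leaf_lookup(tree, n_cond)
            if all(np.max(np.abs(prof - p)) >= config.leaf_sep / 2 for p in profiles):
                break
        else:
            raise ConfigError("could not plant mutually distinct module profiles")
        trees.append(tree)
        profiles.append(prof)
    # TF expression consistent with states: centers at -5/0/+5, sd 0.3
    tf_expr = states * 5.0 + rng.normal(0.0, 0.3, size=states.shape)

    assignment = {g: i % config.n_modules for i, g in enumerate(genes)}
    values = np.empty((config.n_genes, n_cond))
    leaf_maps = [_leaf_lookup(t, n_cond) for t in trees]
    for gi, g in enumerate(genes):
        mus = leaf_maps[assignment[g]]
        values[gi] = mus + rng.normal(0.0, config.noise_sd, size=n_cond)

    expr = pd.DataFrame(values, index=genes, columns=conditions)
    regs = {
        "tf_ids": tf_ids,
        "condition_ids": conditions,
        "expression": pd.DataFrame(tf_expr, index=tf_ids, columns=conditions),
        "states": pd.DataFrame(states, index=tf_ids, columns=conditions),
    }
    truth = SimTruth(module_assignment=assignment, regulator_trees=trees)
    return expr, regs, truth


def _replant_against(rng, tf_ids, states, config, max_tries=200):
    n_cond = states.shape[1]
    for _ in range(max_tries):
        tree, ok = _build_planted(rng, tf_ids, states, config.tree_depth, np.arange(n_cond))
        if ok:
            _assign_leaf_mus(rng, tree, config.leaf_sep)
            return tree, states
    raise ConfigError("could not re-plant a tree against the shared TF states")


def _leaf_lookup(tree, n_cond):
    mus = np.zeros(n_cond)
    for leaf in _collect_leaves(tree):
        mus[np.asarray(leaf["conditions"], int)] = leaf["mu"]
    return mus


def itraq_channel_design(config: SimConfig, timepoints=None) -> pd.DataFrame:
    """Channel layout of the simulated 8-plex runs, one plex per time point.

    The two pooled-reference channels come from the config; the remaining six
    carry three control (25 degC) and three heat (40 degC) replicates.
    """
    timepoints = list(config.timepoints if timepoints is None else timepoints)
    refs = set(config.ref_channels)
    sample_channels = [c for c in range(1, 9) if c not in refs]
    rows = []
    for t in timepoints:
        plex = f"plex_{t}h"
        for c in range(1, 9):
            if c in refs:
                rows.append({"plex": plex, "channel": c, "treatment": "pooled_ref",
                             "time_h": t, "replicate": ""})
            else:
                k = sample_channels.index(c)
                trt = CONTROL if k < 3 else HEAT
                rows.append({"plex": plex, "channel": c, "treatment": trt,
                             "time_h": t, "replicate": f"r{k % 3 + 1}"})
    return pd.DataFrame(rows)


def gen_itraq_peptides(config: SimConfig, timepoints=None):
    """Simulate scan-level 8-plex iTRAQ spectrum reports plus truth.

    Per protein: a log2 baseline per peptide, a planted per-time-point log2
    shift applied to heat channels for ~``de_fraction`` of proteins, a
    per-(plex, channel) bias that central-tendency normalization must remove,
    and the pooled-reference channels carrying the mean of the six sample
    channels (linear scale).  Reporter intensities are lognormal around the
    channel means; the base peak is their sum, so per-channel fractions are
    exactly invertible.  Reporters go missing completely at random at
    ``missing_rate``.

    Returns ``(spectra, channel_design, truth)``.
    """
    rng = np.random.default_rng(config.seed)
    timepoints = list(config.timepoints if timepoints is None else timepoints)
    chan_design = itraq_channel_design(config, timepoints)
    refs = set(config.ref_channels)

    n_shift = int(round(config.de_fraction * config.n_proteins))
    shifted = rng.choice(config.n_proteins, size=n_shift, replace=False)
    shift_sign = rng.choice([-1.0, 1.0], size=n_shift)
    protein_effects = {}
    effects = np.zeros(config.n_proteins)
    for i, s in zip(shifted, shift_sign):
        effects[i] = s  # +/- 1 log2 unit by default, scaled below

    # channel bias per (plex, channel), log2 scale
    bias = {
        (f"plex_{t}h", c): rng.normal(0.0, 0.15) for t in timepoints for c in range(1, 9)
    }

    plo, phi = config.peptides_per_protein
    records = []
    scan_no = 0
    noise = config.noise_sd
    # per-plex channel layout as arrays: heat mask over the 8 channels
    ref_mask = np.array([c in refs for c in range(1, 9)])
    heat_mask = np.zeros(8, bool)
    sample_channels = [c for c in range(1, 9) if c not in refs]
    for k, c in enumerate(sample_channels):
        heat_mask[c - 1] = k >= 3
    bias_by_plex = {
        f"plex_{t}h": np.array([bias[(f"plex_{t}h", c)] for c in range(1, 9)])
        for t in timepoints
    }
    for pi in range(config.n_proteins):
        prot = f"Prot{pi:04d}"
        n_pep = int(rng.integers(plo, phi + 1))
        pep_base = rng.normal(20.0, 1.0, size=n_pep)
        if effects[pi] != 0.0:
            protein_effects[prot] = {int(t): float(effects[pi]) for t in timepoints}
        for t in timepoints:
            plex = f"plex_{t}h"
            for j in range(n_pep):
                pep = f"{prot}_pep{j + 1}"
                # true log2 abundance per channel
                log2_ch = np.full(8, pep_base[j])
                log2_ch[heat_mask] += effects[pi]
                ref_val = float(np.log2(np.mean(2.0 ** log2_ch[~ref_mask])))
                log2_ch[ref_mask] = ref_val
                log2_ch = log2_ch + bias_by_plex[plex]
                n_scans = int(rng.integers(1, 4))
                for s in range(n_scans):
                    scan_no += 1
                    scan_scale = rng.normal(0.0, 0.5)  # scan-to-scan total intensity
                    obs = log2_ch + scan_scale + rng.normal(0.0, noise, size=8)
                    rep = 2.0**obs
                    drop = rng.random(8) < config.missing_rate
                    rep[drop] = 0.0
                    if not np.any(rep > 0):
                        continue
                    records.append(
                        {
                            "scan": f"scan{scan_no:07d}",
                            "peptide": pep,
                            "protein": prot,
                            "plex": plex,
                            "fraction": f"f{int(rng.integers(1, 13)):02d}",
                            "base_peak": float(rep.sum()),
                            **{f"ch{c}": float(rep[c - 1]) for c in range(1, 9)},
                        }
                    )
    spectra = pd.DataFrame(records)
    truth = SimTruth(protein_effects=protein_effects)
    return spectra, chan_design, truth


def gen_qpcr(
    config: SimConfig,
    gene_fold_changes: dict,
    peff: float = 2.0,
    ct_noise: float = 0.0,
    timepoints=(3, 12, 24),
):
    """Simulate qPCR delta-Ct records reproducing requested fold changes.

    Expression is E = Peff^(-dCt) with dCt = Ct_gene - Ct_cons6; heat-sample
    dCt values are back-computed so E_heat / E_ctrl equals the requested fold
    change exactly when ``ct_noise`` is zero.
    """
    if not 1.0 < peff <= 2.0:
        raise ValueError("primer efficiency Peff must be in (1, 2]")
    rng = np.random.default_rng(config.seed)
    rows = []
    for gene, fc in gene_fold_changes.items():
        if fc <= 0:
            raise ValueError("fold changes must be positive")
        for t in timepoints:
            base = rng.normal(2.0, 1.0)
            d_heat = base - np.log(fc) / np.log(peff)
            for r in range(config.n_replicates):
                rows.append(
                    {
                        "gene_id": gene,
                        "Peff": peff,
                        "treatment": CONTROL,
                        "time_h": t,
                        "replicate": f"r{r + 1}",
                        "delta_ct": base + rng.normal(0.0, ct_noise) if ct_noise else base,
                    }
                )
                rows.append(
                    {
                        "gene_id": gene,
                        "Peff": peff,
                        "treatment": HEAT,
                        "time_h": t,
                        "replicate": f"r{r + 1}",
                        "delta_ct": d_heat + rng.normal(0.0, ct_noise) if ct_noise else d_heat,
                    }
                )
    df = pd.DataFrame(rows)
    df["expression"] = peff ** (-df["delta_ct"])
    return df
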