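# Methods

This note records the statistical models, the numerical choices behind them,
what the synthetic-data generators do and do not emulate, and the design
decisions taken where the workflow description left the choice open.

## Poisson mixed-model differential expression

Each gene is fitted independently, per (tissue, time) heat-vs-control
contrast, with a Poisson log-linear model carrying a log library-size
offset, a treatment fixed effect, and independent Gaussian random
intercepts for biological replicate and plate. Testing is per contrast
(e.g. RH heat vs RH control at 3 h); a pooled all-sample model with
interaction terms is deliberately out of scope, matching how the contrasts
are reported.

**Likelihood evaluation.** The marginal likelihood integrates the random
effects out of the Poisson likelihood. Two evaluators exist:

- *Laplace* over the joint random-effect vector, which handles crossed
  replicate × plate structure. Fitting uses the lme4 strategy: the fixed
  effects and random-effect modes are found together by a penalized IRLS
  inner loop (Newton on the joint objective, gradient tolerance 1e-8,
  iteration cap 200), and only the two variance parameters are optimized
  on the outside (L-BFGS-B on the standard-deviation scale, bounded at 0).
  A vanishing variance is implemented as a huge ridge penalty, which
  reproduces the plain-GLM limit smoothly; the plain-GLM boundary fit is
  always computed and kept when it is at least as good, so variance
  estimates legitimately sit at 0.
- *Adaptive Gauss–Hermite* (15 nodes, centred at the per-group conditional
  mode, scaled by the conditional curvature) when a single grouping factor
  is active; the marginal likelihood then factorises into one-dimensional
  integrals. The test suite bounds this evaluator against brute-force
  numeric integration (dense-grid trapezoid with log-sum-exp) at 1e-4 on
  tiny instances; in practice it agrees to ~1e-6.

**Testing and calling.** The LRT statistic 2·(ll_full − ll_reduced) is
clamped at zero (nested fits can cross only through numerical noise) and
referred to chi-square with 1 df — the single treatment coefficient.
Q-values follow Storey's procedure: pi0 estimated on the lambda grid
0, 0.05, …, 0.90 with a cubic polynomial smoother read off at 0.90,
clipped to (0, 1]; for families under 100 tests pi0 is fixed at 1, which
reduces the q-values to Benjamini–Hochberg. A gene is called at q ≤ 0.01
and |log2 FC| ≥ 1, with the fold change taken from the model
(beta_trt / ln 2) on the count scale rather than from RPKM ratios — the
consistent choice given the fitted model, and exposed as a parameter.

## Module networks

TF discretization counts the expression ranges a TF occupies (> 3, < −3,
in between — the cutoffs apply to whatever scale the input matrix is on,
here log2 fold change, and are parameters), runs 1-D K-means with that many
clusters, and maps clusters to the occupied labels by center order. A
single-range TF legitimately gets one constant state.

Trees are grown greedily: at each node, the (TF, query) pair maximizing the
summed Gaussian log-likelihood of the member genes over the two resulting
condition subsets is chosen, accepting a split only when the gain is
positive and both children keep ≥ 2 conditions (`min_leaf_conditions`).
Leaves store the sample mean and the maximum-likelihood variance floored at
1e-4 to avoid degenerate infinite likelihoods. Queries are the two
predicates state == 1 and state == −1; a child may reuse the same TF with
the other predicate. Default `max_depth` is 3. The number of modules K is a
user parameter (the biological analysis this mirrors arrived at 10 modules
from its data, not from a selection rule); empty modules are dropped and K
shrinks.

The fit alternates tree learning and gene reassignment from a K-means start
(k-means++, seeded, 10 restarts). Reassignment moves each gene to the
highest-scoring tree, keeping the current module on ties (then lowest
index). Because a freshly grown greedy tree is not guaranteed to beat the
previous tree on a module's *new* membership, the previous tree is retained
whenever it scores the current members better; this makes the recorded
total-likelihood history provably non-decreasing, which the tests assert on
every run.

## iTRAQ quantification

Scan-level channel intensities are `base_peak × reporter_c / Σ reporters`.
The workflow text this implements describes "dividing the base peak
intensity by the fraction", which is arithmetically implausible (it would
inflate the weakest channels); multiplication by the fraction is the
operation that conserves the base peak (channel intensities sum to it
exactly) and is what is implemented. Scans of the same peptide within a
plex are summed channel-wise before the log2 transform; channels that are
zero after summation become missing values, never −inf.

Which two channels carry the pooled reference is configurable (default 4
and 8); bridging subtracts each peptide's per-plex reference mean.
Central-tendency normalization then shifts every (plex, channel) column so
its median equals the global median. Rrollup picks as reference the peptide
with the fewest missing values (ties: higher median abundance, then input
order), shifts every other peptide by the median difference over shared
samples, and takes the per-sample median; a peptide sharing no samples with
the reference is excluded with a warning.

Per time point, 25 °C vs 40 °C is a one-way ANOVA over replicate channels,
requiring ≥ 2 values per group (otherwise the protein is reported
untestable). Benjamini–Hochberg runs within each time point across proteins
(a global-correction switch exists). Calls need adjusted p < 0.05 and
|log2 FC| ≥ 1, the fold change being mean(40 °C) − mean(25 °C) in log2.

## Integration

Directional overlaps intersect up-sets with up-sets and down-sets with
down-sets; a gene up in one tissue and down in the other is *discordant*,
reported separately and counted in neither common set (the additivity
identity |unique| + |common| = |total| then holds per direction by
construction). The time-point core is the direction-consistent intersection
across all time points; its reported fraction uses the union of all called
genes as denominator by default, with the mean per-time-point set size as
an alternative convention — the source analyses are ambiguous on this
point, and the two conventions give visibly different percentages, so the
choice is a parameter rather than a resolution. ΔCt is defined as
Ct_gene − Ct_cons6 (the sign convention is ours; only the ratio
E_heat/E_ctrl is identifiable). Term enrichment is the one-sided
hypergeometric tail with BH q-values by default.

## Synthetic data

The generators produce exactly the structure the estimators assume, plus a
truth record:

- **Counts**: Poisson with the modelled log-mean; per-gene baselines are
  lognormal around a median count of 60 at a ~1e6 library size (library
  sizes uniform on a configurable range — real per-library depths are much
  larger, but the per-gene count scale, which is what drives the test's
  behaviour, is realistic for moderately expressed genes). Replicate and
  plate effects are drawn independently per gene × level (SD 0.1 by
  default), and plates are laid out in a Latin square over
  (treatment, replicate) so the plate factor is not aliased. True DE genes
  (10% by default) carry a ± ln 2 treatment effect.
- **Module expression**: every module gets a planted regulator tree over a
  shared TF state matrix; TF expression is generated at ±5/0 with SD 0.3 so
  it discretizes cleanly against the ±3 cutoffs; leaf means are spaced by
  `leaf_sep` (default 4) with a random per-module offset so module profiles
  stay mutually distinct (pairwise max difference ≥ leaf_sep/2 enforced);
  member genes add N(0, noise_sd²) noise, default 0.1 — a
  separation-to-noise ratio of 40, well above the ≥ 10 regime the recovery
  tests target.
- **iTRAQ**: lognormal reporter intensities around per-channel means, base
  peak equal to the reporter sum (making the scan-level step exactly
  invertible), per-(plex, channel) bias N(0, 0.15) for the normalization to
  remove, two pooled-reference channels carrying the linear mean of the six
  sample channels, 1–3 scans per peptide per plex, and completely-at-random
  missingness (default 5%). One plex per time point: three control and
  three heat replicate channels around the two references.
- **qPCR**: heat ΔCt values are back-computed from requested fold changes,
  so the round trip is exact at zero Ct noise.

Counts are Poisson, not negative binomial — matching the fitted model; an
overdispersion knob is out of scope, so the calibration results say nothing
about robustness to extra-Poisson variation. Missingness is MCAR only, and
no batch structure beyond the plate factor is simulated. Passing tests
therefore demonstrate correctness and calibration *under the assumed
model*, not robustness to real-data violations of it.

## Problem sizes and calibration targets

The calibration suite uses 2000 genes × 20 seeds for the gene-level chain
(one contrast, 2 treatments × 2 replicates, 2 plates) and 500 proteins ×
20 seeds × 4 time points for the protein chain — sizes at which the
Monte-Carlo error of an average false-discovery proportion is a small
fraction of the nominal levels being checked (1% and 5%). The per-gene
mixed-model fit takes ~8 ms, so the full gene-level calibration runs in
minutes on one core. Tiny-instance oracles (≤ 6 observations for the
likelihood, ≤ 6 TFs / ≤ 12 conditions for tree search) are exhaustive or
numerically exact, so those comparisons are at tolerance 1e-4 or tighter.

## Known limitations

- The Laplace approximation can be slightly anticonservative for very small
  counts; the null-uniformity test (KS on 2000 null genes) bounds the
  practical effect at the simulated operating point.
- With 4 observations and 4 random-effect levels per contrast, variance
  components are weakly identified and frequently estimated at the zero
  boundary; the treatment LRT remains calibrated, but the variance
  estimates themselves should not be interpreted.
- Greedy tree search is optimal only for depth-1 trees (where the tests
  prove it exhaustively); deeper trees are locally optimal.
- Rrollup's protein scale follows the reference peptide, so absolute
  protein abundances are relative quantities; only within-protein contrasts
  (e.g. the 40 °C/25 °C fold change) are meaningful.
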