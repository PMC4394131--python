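# Methods

This note documents the statistical procedures, the synthetic study
conditions, the numerical choices, and what the package's tests do and
do not establish about real data.

## Per-platform differential expression

Sequencing counts are transformed to `log2(CPM + 0.5)`; CPM is
1e6 × count / library size (column sum), and the 0.5 pseudocount avoids
log of zero while keeping the transform monotone.  Microarray inputs
are assumed already normalised on the log2 scale.

For a contrast (a, b) the per-feature statistic is a Welch contrast of
group means on the log2 scale: `logfc = mean_b − mean_a`,
`se = sqrt(s_a²/n_a + s_b²/n_b)`.  Features with zero pooled variance
(possible with discrete low counts) receive an SE floor of 10% of the
median positive SE and are flagged; this prevents infinite statistics
on degenerate features.  A minimum of two samples per group is
enforced.

The p-value uses the Student-t reference with Welch–Satterthwaite
degrees of freedom, and the reported `z` is the probit transform of
that p-value carrying the sign of the fold change,
`z = sign(logfc) · Φ⁻¹(1 − p/2)`.  The design rationale: the cross-grade
combination assumes each per-grade score is N(0,1) under the null.  The
raw ratio `logfc/se` is t-distributed, and at the small group sizes
this package targets (6–14 per group) treating it as normal inflates
the type-I error of the combined test to ≈ 0.07 at a nominal 0.05.  The
probit-of-t definition is the standard way to carry t-statistics into a
Stouffer combination and makes `z` exactly standard normal under the
null at any group size (the test suite verifies the 5% null rate per
platform and for the combined statistic).  The raw Welch ratio is kept
in the `statistic` column; `z → statistic` as the degrees of freedom
grow.

Benjamini–Hochberg adjustment is the standard step-up procedure
(delegated to statsmodels), applied over all features tested on a
platform, and again over the platform-shared features after
combination.

## Cross-grade combination and selection

Over the intersection of feature ids,
`Z_combined = (Z_III + Z_IV)/√2`, two-sided normal p, BH FDR.  The √2
denominator is the Stouffer convention that makes the combined score
standard normal given that the sum of two independent N(0,1) scores is
N(0,2); a `combine_denominator="2"` switch divides by 2 instead for
comparison with analyses that used that scaling (it only rescales the
score, so the selection threshold then acts more conservatively).
Features measured on a single platform cannot be combined and are
reported separately.

Signature rule: FDR < 0.05 and |Z_combined| ≥ 2, partitioned by sign
(positive = up in poor prognosis, since fold changes are poor − good).
The mRNA pool reuses the identical machinery with the selection rule
joint p < 0.05 and ≥ 2-fold combined change, where the combined fold
change is the mean of the per-grade log2 fold changes.

## Target mapping

A (microRNA, gene) pair survives if ≥ 2 of the 3 prediction tables
contain it, the microRNA is in the signature and the gene is in the DE
mRNA pool.  Identifiers are lowercased and stripped of the "hsa-"
prefix before comparison; the restriction to the gene pool is applied
after the per-table lookup, which is set-theoretically identical to
restricting the databases first.  The implementation is checked against
brute-force enumeration over the pair universe.

## Lineage correlation

Stage transitions are the seven consecutive pairs of
ESC, EB, NP, GP, OP1, OP2, OP3, OL.  Per transition and feature:
log2 fold change of replicate means and a Welch two-sample p across
replicates (unadjusted, deliberately permissive per-transition
filtering); a feature passes with p < 0.05 and |log2FC| ≥ 1 (≥ 2-fold
on the linear scale).  Transitions with fewer than `min_passing`
(default 5) passing features are flagged omitted and no correlation is
computed — the degenerate case a plateau between adjacent stages
produces.  Zero replicate variance yields an undefined p; such features
are flagged degenerate and never pass.

Spearman correlations use average ranks for ties; the p-value is the
t-approximation, except for n ≤ 9 where the full permutation
distribution is enumerated exactly.  Constant vectors make ρ undefined
and are reported as NaN.  Transition–contrast correlations are
restricted to the transition's passing features intersected with the
contrast's features and require at least 3 points; control-lineage
vectors carry their own feature subset and go through the same
machinery.

Per-tumor stage similarity is the Spearman correlation of the tumor
profile with each stage mean profile, computed over one explicit shared
feature set for every (tumor, stage) cell, vectorised as Pearson
correlation of column ranks.

## Survival association

The per-stage similarity enters a Cox proportional-hazards model as a
single untransformed continuous covariate, one fit per stage, with no
stratification by grade (the tumor cohort is pooled).  The partial
likelihood is maximised by Newton–Raphson with the Efron tie
correction (lifelines); ties are expected in month-resolution data and
Efron is more accurate than Breslow.  The 95% CI is Wald on the
log-hazard scale, `exp(β ± 1.96·se)`; a constant covariate raises a
degenerate-predictor error and a non-converging (monotone) likelihood a
divergence error with a diagnostic.  The Kaplan–Meier comparison splits
at the median similarity with ties going to the "low" (≤ median) group,
and uses the two-group log-rank test.

## Synthetic study conditions

The generator's defaults are the study geometry: 534 mature microRNAs,
prognosis groups of 6/10 (GIIIA good/poor, sequencing platform) and
13/14 (GBM, microarray), 50 planted prognostic microRNAs at
|log2FC| = 1.5 with concordant sign in the poor group of both grades,
150 platform-shared microRNAs, 3 replicates per differentiation stage,
597 tumors, log-hazard 2 per unit OP1 similarity.  Cut-offs for group
assignment are > 48 months (good, both grades), < 10 months (poor
GIIIA) and < 4 months (poor GBM).

Free parameters not fixed by that geometry were chosen once on
plausibility and identifiability grounds:

* **Counts**: negative binomial with common dispersion 0.2 (typical
  over-dispersion for small-RNA libraries), per-feature baseline means
  log-normal around 200 counts (mature-miRNA libraries concentrate
  reads on a few hundred species; this keeps log2-CPM noise
  approximately Gaussian so the Welch test is calibrated), library
  sizes stratified over a 4-fold log-uniform range (guaranteeing the
  ≥ 2-fold variation the normalisation must absorb).
* **Microarray**: Gaussian on the log2 scale with SD 0.4 around a
  per-feature baseline N(7, 0.7) — level-3-style, already normalised.
* **Stage profiles**: baseline plus marker "bumps" of amplitude 2.5
  (log2): one 20-feature marker block peaked at each of ESC, EB, NP,
  GP, OP1, OL, a shared OP2/OP3 plateau block, shoulder level 0.25 of
  the peak at adjacent stages, plus 40 smooth monotone ramp features.
  All marker blocks live inside the 150 shared features.  The OP2/OP3
  plateau means that transition carries no designed signal, so the
  per-transition filter finds too few changing microRNAs and the
  transition is omitted — the analysis must handle exactly this case.
  Replicate noise SD 0.25 (a separate knob from the cohort microarray,
  as the stage series is its own platform): small enough that chance
  ≥ 2-fold passes stay well below the omission threshold, large enough
  that the significance filter is non-trivial.
* **Planted prognostic set**: the OP1 marker block (up in poor) plus
  30 random non-marker features with random signs.  This single choice
  ties the two halves of the study together: the signature-recovery
  conditions and the lineage-correlation sign structure (poor-prognosis
  tumors over-express OP1 markers ⇒ prognosis fold changes correlate
  negatively with OP1→OP2 and positively with GP→OP1).
* **Tumors**: convex Dirichlet(0.2) mixtures of stage means over the
  shared features, blended with a rank-scrambled copy of themselves by
  a per-tumor distortion drawn from 0.9·Beta(0.4, 0.4), plus N(0, 0.4)
  noise.  The bimodal distortion emulates cohorts containing both
  strongly stage-like and weakly stage-like tumors and is what gives
  the OP1 similarity score enough spread (SD ≈ 0.25) for the Cox
  recovery margin; the stage-specific mixture component is what lets
  the per-stage Cox sweep single out OP1.
* **Survival**: exponential with baseline hazard 0.05/month
  (median ≈ 14 months at the mean similarity) and log-hazard
  `hazard_beta × realized OP1 similarity` — the covariate the analysis
  actually measures, which makes "recover the planted log-hazard" a
  well-posed consistency check (the estimate converges to the planted
  2.0 as the cohort grows; verified at n = 5000).  Censoring is
  independent uniform administrative censoring on (0, H], with H solved
  so that a 30% fraction is censored in expectation at the baseline
  hazard.  An earlier design that censored by scaling event times was
  discarded because it is informative and biases the Cox estimate.
* **mRNA cohorts**: 4000 genes, 400 planted at |log2FC| = 1.5, same
  patients and platforms.  Target tables: 3000 pairs, 40% written into
  ≥ 2 of the 3 tables.  Control lineages: 139-feature fold-change
  vectors drawn independently of everything (SD 1.2).

A single master seed drives named `SeedSequence` sub-streams (design,
cohort, stage, tumor, mrna, targets, control), so every generator is
bit-reproducible and independent of execution order.

## What the synthetic conditions do not show

The generator plants clean, homogeneous effects: Gaussian platform
noise, a common NB dispersion, no batch structure, no correlation
between microRNAs beyond the designed marker blocks, no coupling
between microRNA and mRNA regulation beyond pool membership, and
identifier vocabularies that match exactly across tables.  Passing
tests therefore demonstrate that the *procedures* are correct and
calibrated under their stated assumptions — not that the biological
conclusions transfer to any real cohort, where normalisation artifacts,
annotation mismatches and confounding (e.g. IDH status, which the
pipeline carries only as a contrast label) dominate.

## Problem sizes and runtime choices

Simulation-based checks use the default geometry (534 features, 43
cohort samples, 597 tumors) with 20 replicates for rate-style
assertions and 100 replicates for CI coverage; the acceptance script
uses 5–50 replicates per quantity.  These sizes put every Monte-Carlo
assertion's tolerance at the binomial noise floor while keeping a full
run in seconds.

## Known limitations

* The per-platform test is a defined Welch/probit contrast, not a
  reimplementation of count-model or empirical-Bayes microarray
  pipelines; numerical equality with such tools is not claimed (only
  the (logFC, SE, z) contract the combination needs).
* The exact Spearman p-value enumerates permutations and is available
  only for n ≤ 9; larger samples use the t-approximation.
* `cox_all_stages` fits each stage marginally; it does not adjust for
  the other stages' similarity or for grade.
* The CLI's single-stage subcommands exchange data through TSV, so
  round-trips are limited to float text precision (Python's shortest
  round-trip repr, i.e. exact for these purposes).
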