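# gliomir

Cross-grade prognostic microRNA analysis for high-grade glioma, with
oligodendrocyte-precursor (OP) stage-similarity scoring and survival
association.

## The problem

Grade III anaplastic astrocytoma (GIIIA) and grade IV glioblastoma
(GBM) are usually analysed separately, on different expression
platforms (small-RNA sequencing vs microarray), with small extreme
prognosis groups — so within-grade differential expression has little
power and the two grades' candidate lists barely overlap.  `gliomir`
implements a pipeline that asks whether a *common*, grade-independent
prognostic microRNA signature exists, and whether it reflects an
oligodendrocyte-precursor differentiation state:

1. **Per-grade differential expression.**  Within each grade, poor- vs
   good-prognosis groups are contrasted per microRNA *r* on the log2
   scale, giving a fold change and its standard error, summarised as a
   score `z_r = log2FC_r / SE_r` (p-values use the Welch t reference;
   `z` is its normal-quantile equivalent, so `z ~ N(0,1)` under the
   null at any group size).
2. **Cross-grade combination.**  Under the joint null the two per-grade
   scores are independent N(0,1), so their sum is N(0,2) and
   `Z_combined = (Z_III + Z_IV) / √2` is again standard normal
   (Stouffer combination).  The signature is the set of microRNAs with
   Benjamini–Hochberg FDR < 0.05 and |Z_combined| ≥ 2, split into
   up-in-poor and down-in-poor.
3. **Target mapping.**  Predicted targets of the signature microRNAs
   are kept only if at least 2 of 3 prediction databases agree and the
   gene lies in the differentially expressed mRNA pool (joint p < 0.05
   and ≥ 2-fold combined change).
4. **Lineage correlation.**  For the staged in-vitro differentiation
   series ESC → EB → NP → GP → OP1 → OP2 → OP3 → OL, per-transition
   log2 fold changes are filtered (p < 0.05 and ≥ 2-fold across
   replicates; transitions with too few passing microRNAs are omitted)
   and Spearman-correlated with the prognosis fold changes.  Control
   lineages (ESC→HP, NSC→NP) guard against non-specific correlation.
5. **Per-tumor stage similarity and survival.**  Each tumor's profile
   is Spearman-correlated with every stage mean profile over the
   platform-shared microRNAs; the per-stage similarity ρ enters a Cox
   proportional-hazards model (Efron ties) as a continuous covariate,
   and an above/below-median-ρ Kaplan–Meier comparison with a log-rank
   test gives the non-parametric view.

Because the original cohort data are not redistributable, the package
ships a first-class synthetic-data generator
(`gliomir.simulate`) that emulates every input — negative-binomial
sequencing counts with varying library sizes, Gaussian log2 microarray
intensities, replicate stage profiles with designed marker structure,
tumors as noisy stage mixtures with survival tied to OP1 similarity,
target tables with controlled overlap — all with planted ground truth,
so every stage of the pipeline is testable offline.

## Worked example

```python
import gliomir as g

results = g.run_pipeline(sim_config=g.SimulationConfig(seed=7))
print(results.summary())
```

prints (abridged):

```
Cross-grade prognostic microRNA analysis
========================================================
microRNAs tested (shared across platforms): 534
signature (FDR<0.05, |z|>=2.0): 53 (35 up / 18 down in poor)
DE mRNA pool (joint p<0.05, >=2-fold): 398
predicted targets (>= 2 databases): 117

Stage-transition vs prognosis fold-change correlations (Spearman):
  ...
  GP->OP1    GIIIA_poor_vs_good     rho=+0.686  p=5.29e-08  n=49
  OP1->OP2   GIIIA_poor_vs_good     rho=-0.778  p=2.09e-09  n=41
  OP2->OP3   GIIIA_poor_vs_good     omitted (too few passing microRNAs)
  ...
Cox regression of survival on stage similarity (per-stage):
  ...
  OP1   HR=    7.84  95% CI=(4.98, 12.36)  p=6.68e-19
  ...
  highest hazard ratio: OP1
Median-split Kaplan-Meier (OP1 similarity): log-rank chi2=49.60, p=1.89e-12
```

Reading this: of 534 simulated microRNAs the combined test selects 53
(the generator planted 50 prognostic ones), their targets survive the
2-of-3 database rule, the prognosis fold changes correlate positively
with the GP→OP1 transition and negatively with OP1→OP2 (poor-prognosis
tumors look OP1-like), the OP2→OP3 transition is omitted for lack of
changing microRNAs, and among the eight stages the OP1 similarity score
carries the largest hazard ratio, confirmed by the median-split
Kaplan–Meier comparison.

The same run is available from the shell:

```sh
gliomir run-all --seed 7 --outdir out/
gliomir simulate --seed 7 --outdir inputs/   # write the TSV input bundle
gliomir de --matrix inputs/mirna_counts_GIIIA.tsv --platform counts \
    --annotation inputs/annotation.tsv --out de_giiia.tsv
```

`run-all` writes every stage's table (TSV), a manifest and the summary;
subcommands `simulate`, `de`, `combine`, `targets`, `lineage` and
`survival` run single stages on TSV inputs.

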