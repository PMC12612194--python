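# tallscout

Analysis pipeline for discovering and validating a **non-canonical,
ZBTB16+ lymphoblast state** in childhood T-cell acute lymphoblastic
leukaemia (T-ALL), written for computational biologists working with
single-cell and bulk transcriptomes of leukaemia cohorts.

Refractory T-ALL — disease with ≥5% blasts in marrow after induction
chemotherapy — cannot be predicted at diagnosis. A distinctive blast
population marked by *ZBTB16* (PLZF), the transcription factor that
switches T-cell differentiation toward innate-like lymphocytes, is
enriched in refractory disease. `tallscout` implements the full analysis
chain around that observation:

1. **Cell QC and normalisation** — keep cells with >300 expressed genes,
   >1000 total counts and <15% mitochondrial reads; scale to 10,000 counts
   and log-transform; pluggable clustering with marker-based annotation.
2. **Blast census** — detection-based ZBTB16 positivity (raw count ≥ 1),
   per-sample positive fractions, and a propeller-style moderated t-test on
   logit-transformed proportions, logit((x + ½)/(n + 1)), with
   empirical-Bayes variance shrinkage across cell states.
3. **Pseudo-bulk differential expression** — sum counts per
   (sample × population), keep libraries >100,000 reads and genes with
   logCPM ≥ 0.5 in ≥10% of samples; per-gene negative-binomial GLM with
   log-library offsets, Cox–Reid dispersion estimation shrunk toward a
   mean–dispersion trend, likelihood-ratio tests against a moderated
   F reference, BH correction at 0.05. Includes the ordered-group linear
   trend test (day-0 responsive → day-0 failure → day-28 failure) and a
   Wilcoxon rank-gene test for cluster-vs-rest comparisons.
4. **Gene-module derivation and scoring** — intersect the trend-increasing
   and ZBTB16+ vs ZBTB16− upregulated gene sets, then filter for
   specificity (expressed in <3% of cells in ≥6 responsive patients),
   sensitivity (>2% of ZBTB16+ cells in ≥4 induction-failure patients) and
   leave-one-out score contribution. Cells are scored by the Scanpy module
   score (mean expression minus expression-matched controls); bulk samples
   by a singscore-style normalised mean rank in [−0.5, 0.5].
5. **Surface-target discovery** — blast-upregulated genes filtered by
   expressed-cell fractions and a reference atlas of conventional T-cell
   types, restricted to cell-surface genes (GO:0009897 snapshot).
6. **Reference-similarity mapping** — multinomial elastic-net logistic
   regression (α = 0.99, cross-validated penalty) scoring query cell types
   against ZBTB16+/ZBTB16−/control classes.
7. **Cohort outcome validation** — blast-content filter (<60% excluded),
   one-sided rank-sum tests across day-28 MRD categories, tertile
   stratification at the 33.33%/66.67% quantiles, Kaplan–Meier curves with
   Greenwood intervals, log-rank tests, and Cox proportional-hazards models
   (Efron ties) with tertile or unit-variance-scaled covariates.
8. **Clonal projection** — substitution quality filters (ASMD ≥ 140,
   CLPM = 0, ±10 bp indel exclusion, depth bounds, binomial background-noise
   test at BH q < 0.05), per-cell copy-number posteriors from phased allele
   counts (call at posterior ≥ 0.95), cancer cell fractions
   CCF = VAF·(ρ·CN + 2(1−ρ))/(ρ·m), and clone/topology assignment
   (linear vs independent vs shared precursor) with per-cell labels.

A seeded synthetic-data module generates single-cell cohorts, bulk survival
cohorts, allele-count tables and two-clone variant structures with the
statistical properties each stage assumes, so the whole pipeline is
testable without access to controlled patient data.

## Worked example

```python
import numpy as np
import tallscout as ts
from tallscout import outcomes as oc

# single-cell arm: simulate, QC, normalise, annotate, derive the module
cfg = ts.SimConfig(seed=1)
cells, truth = ts.simulate_sc_cohort(cfg)
cells, report = ts.qc_filter(cells)
cells = ts.normalize_log(cells)
states = truth.cell_truth.loc[cells.obs_names, "latent_state"]
cells.obs["annotation"] = np.where(states == "normal", "T", "blast")
module, trend, contrast = ts.derive_module_pipeline(cells, seed=0)
print(f"QC retained {report.n_retained}/{report.n_input} cells")
print(f"module: {len(module.genes)} genes, first five: {module.genes[:5]}")

# bulk arm: score the module, test MRD groups, fit survival
counts, samples, _ = ts.simulate_bulk_cohort(cfg)
cohort = oc.SurvivalCohort.from_counts(counts, samples)
scores = ts.score_bulk(cohort.logcpm, module)
mrd = oc.mrd_group_test(scores, cohort.samples["mrd_category"])
print(f"refractory vs lowest-MRD one-sided p = {mrd.loc[0, 'p']:.2e}")
df = cohort.samples[["os_time", "os_status"]].copy()
df["score"] = scores
cox = oc.cox_fit(df, "os_time", "os_status", ["score"],
                 encode={"score": "tertile"})[0]
print(f"per-tertile HR = {cox.hazard_ratio:.2f} "
      f"(95% CI {cox.ci_low:.2f}-{cox.ci_high:.2f}), n = {cox.n}")
```

prints

```
QC retained 8069/8700 cells
module: 28 genes, first five: ['ZBTB16', 'G0004', 'G0028', 'G0003', 'G0015']
refractory vs lowest-MRD one-sided p = 1.44e-52
per-tertile HR = 1.90 (95% CI 1.72-2.09), n = 1095
```

The derived module recovers the planted ZBTB16+ programme (28 of 30 genes,
no false members), its bulk score separates refractory from responsive MRD
categories, and the Cox model recovers the simulated hazard ratio of 2 per
score tertile.

A command-line interface mirrors the library
(`tallscout simulate|preprocess|census|de|score-bulk|cohort|clones`).

## Layout

```
src/tallscout/
  simulate.py     seeded synthetic cohorts (single-cell, bulk, alleles, clones)
  preprocess.py   QC, normalisation, clustering/annotation
  census.py       ZBTB16 positivity, census, moderated proportion test
  pseudobulk.py   aggregation, gene filter, NB GLM DE, trend & Wilcoxon tests
  signature.py    module derivation cascade, cell and bulk scoring
  targets.py      surface-target filter cascade
  similarity.py   elastic-net similarity mapping
  outcomes.py     MRD tests, tertiles, Kaplan–Meier, Cox
  clonal.py       variant filters, CN posteriors, CCF, clone assignment
  cli.py          thin command-line wrapper
docs/methods.md   model and design notes
```
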