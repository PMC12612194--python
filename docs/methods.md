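# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `tallscout`.

## The analysis problem

In childhood T-ALL, refractory disease (≥5% marrow blasts after four weeks
of induction) identifies a very-high-risk group that cannot currently be
recognised at diagnosis. The pipeline quantifies a non-canonical blast
state marked by *ZBTB16* expression: it measures the state in single cells
(census and proportion testing), distils it into a transferable gene
module (pseudo-bulk differential expression plus a filter cascade), scores
the module in bulk cohorts with outcome data (MRD categories, survival),
asks what normal lymphocyte the state resembles (regularised logistic
regression against reference classes), proposes surface antigens
(expressed-fraction filter cascade) and tests whether the state is a
distinct genetic lineage (allele-specific copy-number projection and clone
assignment in single cells).

## Statistical components

### QC, normalisation, annotation

Cells pass QC iff expressed genes > 300, total counts > 1000 and
mitochondrial fraction < 0.15 — all strict inequalities, and the
mitochondrial fraction is computed on raw counts. Rejections are
attributed with the fixed precedence genes → total → mito so the report
partitions the input. Normalisation scales each cell to 10,000 counts
followed by natural log1p (configurable in principle to log2; natural log
is the ecosystem convention); raw counts are kept in `layers["counts"]`
because positivity calls, pseudo-bulk sums and the expression filters all
operate on raw counts. No batch correction is applied, preserving
between-leukaemia variation. Clustering is deliberately pluggable (k-means
on PCA scores by default, Leiden via scanpy as an alternative): the
downstream statistics consume only cluster labels, and tests inject
ground-truth labels, so the community-detection algorithm is not part of
the scientific contract. Cluster annotation assigns each cluster the label
whose marker set has the highest mean normalised expression.

### Proportion testing (propeller-style)

Per sample, the ZBTB16+ blast proportion is transformed as
logit((x + ½)/(n + 1)), defined at 0% and 100%. The two-group comparison
uses a moderated t: per cell state the pooled within-group variance s² on
df = nₐ + n_b − 2 degrees of freedom; across states an inverse-gamma prior
(d₀, s₀²) is fitted by moment matching on log s² (digamma/trigamma
inversion, the limma fit); the posterior variance
(d₀s₀² + df·s²)/(d₀ + df) gives a t on df + d₀ degrees of freedom. With a
single cell state no across-unit variance distribution exists and the test
falls back to the ordinary pooled-variance t (equivalently d₀ = 0); the
prior df can also be fixed by the caller. Two-sided p-values, BH-adjusted
across states. Monte-Carlo null simulations (binomially sampled
proportions with between-sample beta variation, 8-vs-13 samples) put the
empirical type-I error at nominal 0.05 within [0.035, 0.065].

### Pseudo-bulk NB differential expression

Counts are summed over (sample × population); libraries of 100,000 reads
or fewer are dropped (strict >). Genes are retained when
logCPM = log2((count + ½)/(libsize + 1)·10⁶) ≥ 0.5 in at least
⌈0.10·n⌉ samples (an `average=True` variant applies the cohort-style
mean-logCPM rule instead). Per gene a negative-binomial GLM with log link
and log-library offsets is fitted by IRLS. Dispersion: per-gene Cox–Reid
adjusted profile maximum likelihood (the −½ log det(XᵀWX) penalty corrects
the downward bias of plug-in MLE), then shrinkage of log-dispersions
toward a lowess mean–dispersion trend with a prior weight of 10 df against
the residual df. Testing: likelihood ratio of the full vs reduced design.
With estimated dispersions the statistic is referred to F(1, residual
df + prior df) — the moderated small-sample reference; the chi-squared
limit ignores dispersion-estimation uncertainty and measured ~0.07
empirical type-I at 6-vs-6 samples, while the F reference restores
0.047–0.056 across independent null realisations. With a user-fixed
dispersion the chi-squared reference is used. BH adjustment, significance
at adjusted p < 0.05.

The "linearly increasing across the three sample groups" analysis is a
linear trend on ordered codes 0/1/2: three groups cannot support a
nontrivial spline basis, so trend-on-codes is the faithful reduction; a
positive coefficient with adjusted p < 0.05 defines an increasing gene.

The cluster-vs-rest ranking uses a vectorised Wilcoxon rank-sum z with
tie correction and continuity correction, implemented directly so that
fully tied genes return z = 0, p = 1 exactly.

### Module derivation and scoring

Candidates are the intersection of (i) trend-increasing genes and (ii)
genes upregulated in ZBTB16+ induction-failure vs ZBTB16− responsive
pseudo-bulks. Three filters follow. "Expressed in" always means raw count
≥ 1, consistent with the census positivity call. Filter 1 (specificity):
expressed in <3% of day-0 blasts in at least six responsive patients.
Filter 2 (sensitivity): expressed in >2% of ZBTB16+ blasts in at least
four induction-failure patients. Filter 3 (contribution): recompute the
single-cell score with each gene left out; keep genes whose exclusion
reduces the ZBTB16+/ZBTB16− standardised mean difference by more than τ.
τ = 0 is the default — any reduction in separation means the gene
contributes; because the score is a mean over genes, this retains genes
contributing at least roughly half the average separation, which is the
intended "maximally impactful" behaviour. Quota shortfalls (fewer patients
than a filter requires) raise errors naming the quota, and an empty module
at any stage is an explicit error. Filters 1–2 are computed on the
discovery cohort only.

Cell scores use the Scanpy module score: mean normalised expression of the
module minus the mean of control genes drawn per module gene from its
average-expression bin (25 bins, 50 controls per gene, seeded — the seed
is a required argument precisely so scores are reproducible). Bulk scores
are singscore-style: per sample, rank all n genes ascending with mid-rank
ties; with mean module rank R̄ over m genes the score is
(R̄ − R̄min)/(R̄max − R̄min) − ½ where R̄min = (m+1)/2 and
R̄max = (2n−m+1)/2, hence exactly ±0.5 at extremal placements and
invariant to any monotone within-sample transform.

### Surface targets

Starting from genes upregulated in blasts vs the patient's own normal
T cells at adjusted p < 0.05 (the DE threshold is not separately stated
for this step; 0.05 matches the DE contract), candidates must (pan-T-ALL
list) be expressed in >15% of blasts, or (ZBTB16+ list) in <15% of day-0
responsive cells and >10% of ZBTB16+ cells; in both lists expressed in
<10% of cells in at least ten conventional reference T-cell types, and be
cell-surface genes. The bundled GO:0009897 list is a hand-curated
synthetic snapshot (see the file header) and is overridable by a real
ontology export; reference "conventional" types are declared in the
reference metadata, never inferred.

### Similarity mapping

Multinomial logistic regression with elastic-net penalty, mixing
α = 0.99 (nearly lasso, strong regularisation), on unscaled log-normalised
expression over all shared genes. The penalty strength is chosen by seeded
stratified cross-validation (10-fold by default) minimising multinomial
deviance; class weights are uniform with an inverse-frequency option.
Query cells are aligned to the training genes (absent genes imputed as
zero, with a warning) and each query type is summarised by its mean
predicted class probabilities, re-normalised to the simplex.

### Cohort outcomes

Samples with blast content strictly below 60% are excluded before any
statistic. MRD-category comparisons are one-sided Wilcoxon rank-sum tests
with the alternative "higher score in the higher-MRD group". Tertiles are
cut at nearest-rank 33.33%/66.67% quantiles — deterministic under ties;
the mid tertile is retained but excluded from top-vs-bottom contrasts; an
all-equal score vector is an explicit error. Kaplan–Meier estimation with
Greenwood 95% intervals and the two-group log-rank test come from
lifelines, as do Cox models (Efron tie handling — preferable to Breslow
under heavy ties; note Efron is itself an approximation, so duplicating
every record changes the estimate at O(1/n) rather than leaving it exactly
fixed). "Continuous scaled" covariates are standardised to unit variance
so hazard ratios are comparable across different scores; the ETP covariate
can merge near-ETP into ETP or exclude those samples.

### Clonal projection

Substitutions pass when ASMD ≥ 140, CLPM = 0, not within 10 bp of an
indel, per-sample depth within [8, 1000] (the depth bounds are artifact
defaults — the source pipeline states none — and are configurable), and a
one-sided binomial test of pooled alt reads against the site-specific
background error rate rejects noise at BH q < 0.05. Per-cell copy-number
posteriors treat the phased major-allele count as binomial with expected
BAF 0.5 (diploid), 1 − ε (copy-neutral LOH, ε = 0.01 sequencing-error
default) or 2/3 (2:1 gain) under a uniform prior; a state is called at
posterior ≥ 0.95, cells without reads are "uncalled". Phasing is an input
(from the high-purity sample's haploblocks), never inferred here.
CCF = VAF·(ρ·CN + 2(1 − ρ))/(ρ·m) with purity ρ and m mutated copies,
clipped to [0, 1.05]; m defaults to 1 and is otherwise chosen from
{1, …, CN−1} by binomial likelihood. Clone assignment declares a variant
present in a sample when CCF ≥ 0.10 and alt reads ≥ 3 (configurable
artifact defaults), partitions variants into shared/precursor and
sample-private sets, and reports the phylogeny the presence pattern
satisfies: private sets on both sides with a shared set → shared
precursor; disjoint sets → independent; shared plus one private set →
linear. Cells are labelled from their clone-informative variant reads and
copy-number calls; cells carrying private evidence of both clones are
flagged "ambiguous", never silently assigned. TCR labels enter only as
independent evidence, summarised as an agreement fraction. Coordinates:
variants 1-based (VCF-style), segments 0-based half-open (BED-style).

## The synthetic-data generator

The generator emulates the discovery-cohort design: 8 responsive and 13
induction-failure children, day-28 samples for 8 of the failures, ~26%
normal cells per sample, and planted latent ZBTB16+ fractions of 0.67%
(responsive day 0), 30% (failure day 0) and 97.6% (failure day 28) — the
boundary rates match the published P058 counts (65/9668 and 692/709).
Counts are gamma-Poisson (negative binomial, shared dispersion 0.5) with
gene-level means scaled by per-cell library sizes (log-normal, median
≈ 4,900 counts) and mitochondrial budgets (beta, mean 5%); mitochondrial
genes are simply the first ten identifiers flagged `MT-`. Each generator
draws from its own CRC32-derived RNG stream, so adding one generator never
perturbs another, and a fixed seed fixes every output byte.

The planted ZBTB16+ programme is an on/off cell state: module genes are
detected in ~1% of canonical blasts (safely below the 3% specificity
filter, as for the real module's genes) and switch to a shared on-state
level (~40% detection, log2 fold change 6 on means, narrow 0.85–1.15
jitter) in ZBTB16+ cells, with ZBTB16 itself at its observed on/off
detection rates (~0.7% → ~97.5%). Two deliberate design points: the
fold-change regime is taken from the observed detection-rate switch rather
than a generic DE effect size, because a weak (~4×) plant on a near-zero
baseline is not a genuine contributor to a mean-based module score — its
exclusion *raises* the group separation, so it is not a module member
under the method's own leave-one-out definition; and module members share
a common on-state level because each real module gene passed the same
maximal-impact filter. Problem sizes (300 cells/sample, 1,500 genes) are
scaled down from the real cohort to keep simulations tractable; they are
package defaults, not scientific claims.

The bulk cohort (1,175 samples, matching the analysed trial-cohort size)
mixes the ZBTB16+ and ZBTB16− expression profiles with a weight that rises
across the five MRD categories (mean weights 0.01 → 0.45, beta-distributed
per sample); survival times are exponential with the hazard multiplied by
the configured ratio (default 2.0) per true-mixing-weight tertile, with
independent exponential censoring truncated at 10 years of follow-up, and
~12% of samples drawn below the 60% blast-content threshold so the
exclusion rule is exercised. Allele counts are binomial over Poisson
per-cell depths under the three copy-number states. The clonal-structure
generator plants a precursor clone plus two private clones across a
high-purity day-0 sample (60×) and a low-purity (5%) day-28 sample
sequenced deep (429×) — at standard depth the refractory clone's variants
would fall below any sensible alt-read threshold, which is exactly why the
real refractory sample was sequenced deep.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, gene–gene correlation beyond the planted programme, realistic
gene-length or GC structure, non-exponential hazards, subclonal copy
number within a clone. Passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the stated
models, not robustness to those artefacts.

## Numerical choices

- logCPM prior count 0.5 and libsize + 1 denominator (edgeR convention).
- Gene-filter quota ⌈0.10·n⌉; "at least 0.5" is a weak inequality.
- Dispersion search on log α ∈ [−10, 4], golden-section to xatol 0.02;
  all-zero genes are assigned dispersion 0.1 and p = 1.
- IRLS convergence at relative log-likelihood change 10⁻¹⁰, ridge 10⁻¹⁰ on
  the normal equations; singular designs raise.
- Trigamma inversion by Newton iteration (50 steps, relative 10⁻⁸).
- Tertile cut: nearest-rank, ties resolved by ≤-assignment to the lower
  group (deterministic).
- Elastic-net fits use saga with tol 10⁻³ and a small C grid by default;
  the full-shrinkage limit (C → 0) returns prior-like constant
  probabilities up to solver tolerance.
- CN posterior uses log-likelihoods with −∞ guards so ε = 0 degenerate
  states are handled exactly.
- Module control-gene sampling, CV fold assignment and every simulation
  take explicit seeds.

## Limitations

- The NB engine reproduces the *contract* of the quasi-likelihood
  pseudo-bulk workflow (calibrated p, BH at 0.05), not edgeR's exact
  numerics; no TMM-style composition normalisation is applied, so offsets
  should be true sequencing depths when composition shifts are extreme.
- The published 29-gene module, trial-cohort hazard ratios and cohort
  p-values depend on controlled patient data and are out of reach by
  construction; the pipeline validates against planted ground truth
  instead.
- Filter 3's τ and top-k behaviour, the original spline df, and the
  variant-presence thresholds are under-determined by the source
  description; all are exposed as configuration with the defaults argued
  above.
- The similarity model uses all shared genes unscaled; no HVG selection or
  embedding-based transfer is attempted.
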