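# Methods

This note documents the models, defaults and numerical choices behind
`empflow`, and what the synthetic validation does and does not establish.

## Data model and normalization

Counts are non-negative integers, cells × genes. The normalized layer is
`log2(1 + counts · 10⁴ / library)` (CP10K-log2), a deterministic function
of the counts, so it can be recomputed bit-identically at any time. CP10K
was fixed deliberately: the ±0.2 EMP-state thresholds are only meaningful
if scores live on a comparable scale across sequencing platforms with very
different depths, and depth-normalized log expression achieves that. Gene
identity is symbol-keyed; duplicate symbols on input are made unique by
suffixing (`-1`, `-2`, …) and logged. Gene coordinates are 1-based; the
chromosome order is numeric-aware (1–22, X, Y, then others). An all-zero
cell is tolerated when loading (its normalized row is zero) but rejected by
the explicit `normalize` operation, which is the contract-checking entry
point.

## Gene-set scoring and EMP states

A signature score is the mean normalized expression over the signature
genes minus the mean over a control pool, with controls drawn per signature
gene from its expression-abundance bin (equal-occupancy bins over the
gene-mean ranking; defaults 25 bins, 50 controls per gene, drawn with
replacement so small bins are never exhausted). Control-matching on
abundance centers scores near zero for an arbitrary gene set, which the
fixed ±0.2 band presupposes; on a constant matrix every score is exactly 0.
Each signature's control draw is seeded from `(seed, crc32(signature
name))`, which makes `compute_emp` exactly antisymmetric under swapping the
epithelial and mesenchymal signatures.

`EMP = score_mes − score_epi`; positive values mean more mesenchymal than
epithelial. The intermediate band is closed (`[−0.2, 0.2]`), reading the
printed range as inclusive; the boundary behavior is pinned by tests at
−0.2, 0.2 and 0.2000001.

## Hurdle differential expression

Two components share one design matrix: ridge-penalized logistic
regression (Newton iterations, penalty ε = 1e-3 on all coefficients) for
`1{y>0}`, and OLS with ML variance for `y | y > 0`. The penalty makes the
logistic fit well-defined under complete separation; both the full and the
reduced design carry the same penalty, so the penalized LRT statistic is
non-negative by nested optimization. Two deliberate refinements:

* **Uninformative components carry no df.** A gene detected in every cell
  (or none) has a constant detection indicator; its logistic component can
  contribute no evidence about any covariate, so it contributes neither
  statistic nor degrees of freedom. Without this rule the combined χ²
  reference is conservative for saturated genes (measured type-I error
  ≈ 0.03 instead of 0.05 on deep-platform simulations). Similarly, the
  continuous component is absent when fewer than two cells express the
  gene.
* **Symmetric contrast coding.** `run_de` codes the two-group contrast as
  ±1/2 rather than 0/1. Under dummy coding, exchanging the group labels
  shifts the penalized intercept and changes the fit at order ε; with
  symmetric coding the label exchange maps β₁ → −β₁ and the test is
  exactly invariant, as it should be.

log2FC is the difference of group means of the normalized layer (A − B);
the default significance rule is raw p < 0.05 with |log2FC| > 0.5, with a
flag (`use_adjusted`) for BH-adjusted p instead — the raw-p variant is the
default because the joint fold-change condition already suppresses most
null calls at panel sample sizes, and the null simulations confirm FDR
control at the defaults. An optional cell-detection-rate covariate is not
included by default; the standard adjustment here is the tumor model.

Wilcoxon (exact enumeration when n+m ≤ 20 and tie-free, tie-corrected
normal otherwise) and Fisher's exact test are provided as the simple
two-group alternatives; they delegate to scipy behind the module surface
and are pinned by enumeration oracles in the tests.

## Consensus signatures

Per-model DE contrasts metastasis vs primary within one tumor model (no
covariate needed inside a model); models with fewer than 10 metastatic
cells are excluded and reported — 10 is a hard boundary (≥ 10 passes). A
gene enters a potential-group signature iff it passes the thresholds in
the stated direction in ≥ 2 models of the group; the sharing histogram
(exclusive-to-1, shared-by-k) is emitted alongside. Group-vs-rest DE on
primary tumors pools all cells of the *other* potential groups as the
comparison (per-tumor-pairwise comparison is possible by calling `run_de`
directly but is not the default). Cross-platform consensus is plain set
intersection per label with provenance recorded. All set operations are
checked against brute-force scans, and growing `min_models` can only
shrink a signature.

## Peak profiles

For one gene, expressing cells are ordered by EMP and smoothed with a
centered moving average whose window is a fraction of the expressing cells
(default 0.3, a loess-like neighborhood; window ends shrink symmetrically).
The "peaks in intermediate" flag treats the maximum as a plateau: all
positions within 5% of the curve amplitude of the maximum. The flag is
true iff the curve is not flat and the plateau intersects the closed band
at a strictly interior position. The plateau rule exists because a noisy
bump has a flat top — the literal argmax of the smoothed curve jitters by
tens of cells, which is meaningless; a flat curve or an end-only maximum
remains "not peaked" (so monotone epithelial/mesenchymal genes are never
flagged).

## Preranked GSEA

The enrichment score is the signed maximum deviation of the weighted
running sum (hit increments ∝ |stat|^weight normalized over hits, miss
decrement 1/(N − N_hits)); weight 1 is the default, weight 0 gives the
classic KS statistic used by the enumeration oracles. The null is
gene-label permutation: size-matched random sets drawn from the ranking
(rankings arrive preranked, so phenotype permutation is not available).
NES divides ES by the mean |null ES| of the same sign;
p = (1 + #{same-sign null at least as extreme}) / (1 + n_perm), so the
attainable minimum is 1/(1+n_perm); FDR pools sign-normalized null NES
across sets. ES is permutation-free and therefore seed-independent.

## CNV profiles

Per gene, normalized expression is centered by the all-cell mean (a
tumor-only panel has no normal reference; an external per-gene reference
vector is accepted), clipped to ±3, smoothed with a 101-gene moving
average that hard-breaks at chromosome boundaries (symmetric truncation at
ends, output length preserved), then median-centered per cell. Compartment
comparison correlates the pseudobulk (cell-mean) profiles of primary vs
metastasis within each model; R² = r². Adding a constant to one cell's
expression leaves its profile unchanged (exactly so when clipping is
inactive).

## Survival

Kaplan–Meier is the product-limit estimator over distinct event times;
log-rank uses observed-minus-expected with the hypergeometric variance at
each distinct event time (k-group form; two-group χ² equals the squared
standardized O−E sum). Stratification scores each patient by the mean
expression of the signature genes present and splits at the cohort median
with ties to the low group; KM-plotter-style best-cutoff scanning is
intentionally out of scope. Subtype-stratified analysis repeats this
within each subtype with ≥ 20 patients. One caveat discovered during
testing: appending a subject censored after the last event time *does*
change the log-rank statistic (the subject is at risk at every earlier
event time); the implementation follows the standard formula and matches
lifelines on exactly that scenario.

## Association statistics

PCA runs on the top dispersion-ranked genes (default 2000) of the centered
normalized matrix via SVD, with a deterministic sign convention (the
largest-|loading| gene of each component is made positive). EMP–PC
correlations use per-tumor PCA (within-tumor variation); the EMP vs
metastatic-potential correlation encodes low/moderate/high as 1/2/3 and
correlates per-tumor mean EMP (one point per tumor — the per-tumor reading
of an ambiguous choice, documented here). Paired-compartment and
cross-platform reproducibility use one point per model (mean EMP per
side), Pearson r, and an OLS fit with a t-based 95% CI on the slope.

## Metastasis quantification

Foci classes are micro (< 10 cells), intermediate (10–100, inclusive) and
macro (> 100). The potential call makes the qualitative judgment explicit
and configurable: low iff density < 0.05 foci/mm² and no macrometastasis;
high iff ≥ 3 macrometastases or density ≥ 0.5 foci/mm²; moderate
otherwise. The rule that fired is reported, and the call is monotone —
adding foci can never move a tissue from high toward low.

## The synthetic panel

The generator emulates a matched primary/metastasis xenograft panel
profiled on two platforms, with defaults chosen once as the study
conditions:

* 10 tumor models (4 low / 3 moderate / 3 high metastatic potential),
  60 primary cells per model; metastatic yield scales with potential
  (0.2 / 0.6 / 1.2 × the primary count) — metastatic cells are rare in
  poorly metastatic models, which also makes the tissue contrast
  model-imbalanced, the very situation the tumor-model covariate exists
  for.
* A latent axis t ~ Beta(a, b) per cell, with (a, b) = (2,6)/(4,4)/(6,2)
  for low/moderate/high potential (means 0.25/0.5/0.75): a continuum with
  potential-dependent skew, no generative law being claimed for real data.
* 1200 genes: 60 epithelial (mean ∝ 1−t), 60 mesenchymal (∝ t), 30
  intermediate markers (Gaussian bump at t = 0.5, σ = 0.15, sized to the
  ±0.2 band after scoring), 40 tissue genes (± 1 log2 in metastatic
  cells, alternating sign so library sizes stay balanced), the rest
  background. Background baselines are lognormal with sdlog 1.5 — the
  orders-of-magnitude abundance spread of real scRNA-seq, giving a proper
  detection-fraction spectrum; program genes sit at higher baselines, as
  markers do.
* Per-model lognormal gene offsets (sdlog 0.3) provide batch structure;
  one CNV segment per model (120 genes, ×2 or ×0.5, planted on
  background-only chromosomes, shared between compartments by default).
* Counts are gamma-Poisson (NB) with shared dispersion θ = 10 around
  library-scaled relative means; libraries are lognormal around 5·10⁴
  (plate) or 5·10³ (droplet), and droplet entries suffer 20% extra
  dropout. Both platforms render the *same* latent draw, so cross-platform
  consensus has a single ground truth.

The survival generator draws a latent score s ~ N(0,1), expresses it in
the signature genes plus unit Gaussian noise, and draws exponential event
times with rate 0.02·exp(β·s) per month (median ≈ 35 months at β = 0);
with probability `censor_rate` a patient also has a Uniform(0, 120 months)
censoring time. Subtypes are multinomial.

What the generator does **not** emulate: ambient RNA, doublets, UMI
duplication, per-gene dispersion, cell-cycle structure, real gene–gene
correlation beyond the planted programs, or any real genome geometry.
Passing the recovery suite therefore shows the *statistics* behave as
designed under the planted model — calibrated nulls, recovered effects,
reproducible consensus — not that biological conclusions transfer to any
particular real dataset.

## Validation sizes and determinism

The acceptance checks use three 2,000-gene single-platform null panels for
hurdle calibration, the default panel for recovery, and 200 survival
replicates at n = 400 — sizes chosen so the whole validation runs on a
single CPU in a few minutes while keeping Monte-Carlo error well inside
the asserted bands. Every random step flows from one integer seed
(per-stage seeds derived via `numpy.random.SeedSequence`), and the
pipeline's run report checksums every output file; rerunning with the same
config reproduces identical checksums.

## Known limitations

* The hurdle LRT is asymptotic; on very small groups (tens of cells) the
  χ² reference is approximate. The ridge penalty biases coefficients
  slightly toward zero (order ε).
* The GSEA null is gene-label permutation only; NES magnitudes are not
  comparable across tools with phenotype-permutation nulls.
* CNV profiles are relative to the panel's own mean expression; absolute
  copy number and subclonal structure are out of scope.
* The scoring control pool is sampled, so scores carry a small seeded
  sampling variance; increasing `n_ctrl` shrinks it.
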