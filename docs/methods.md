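# Methods

This note documents the statistical models behind `secretomics`, the
defaults and why they were chosen, the numerical conventions, and the
limits of what the synthetic-data tests demonstrate.

## Synthetic study design

The generator (`secretomics.synthdata`) emulates the three inputs of a
CM-secretome / tissue-atlas / serum discovery study with known ground
truth. Its defaults are the study conditions the package is designed
around, not tuning knobs:

* **CM protein-groups matrix.** 742 proteins, 3 cell types (Visc, SubQ,
  Brown) × 3 replicates. Per-protein baseline log₂ intensity ~
  N(25, 2²) (MaxQuant LFQ intensities typically span ~2²⁰–2³⁰), replicate
  noise SD 0.4 log₂ units. A fraction (default 0.6) of proteins carry a
  cell-type-specific shift of 3 log₂ units in one randomly chosen cell
  type. 18.6% of proteins are flagged as reverse hits, contaminants or
  only-identified-by-site (the contamination level typical of
  FBS-supplemented CM experiments), leaving 604 after QC exclusion.
* **Missingness.** Each replicate value is dropped independently with
  probability `expit(β₀ − β₁·log₂x)` (defaults β₀ = 23, β₁ = 1), making
  low-abundance values preferentially missing (MNAR) with an overall
  dropout around 15–20%. Missingness is modelled at the replicate-value
  level, not per protein: the ≥2-of-3 detection filter is only meaningful
  when individual replicates can drop out.
* **iBAQ layer.** iBAQ = LFQ × a per-protein log-normal scalar. iBAQ
  divides intensity by a per-protein theoretical peptide count, so a
  per-protein constant is the right structure; the pipeline uses iBAQ only
  for abundance ranking and Σ iBAQ, never for inference.
* **Tissue atlas.** 300 genes × 88 tissues (two adipose) × 3 replicates,
  baseline N(6, 1²) log₂ expression with replicate SD 0.3. Twenty planted
  genes are elevated by 6 log₂ units in both adipose tissues; all other
  genes are exchangeable across tissues. 88 tissues give the T − 2 = 86
  pairwise comparisons of the reference worked example.
* **Planted adipokines.** Five genes are simultaneously CM-detected
  (placed high in the abundance distribution so dropout cannot hide
  them), atlas-planted, and serum-detected. Planted adipose genes that
  are *not* adipokines are drawn from an atlas-only gene pool, so
  enrichment alone can never create a spurious candidate; the serum set
  contains all adipokines, 30% of the other CM genes, and a few
  non-enriched atlas-only genes.
* **Secretion annotations.** Routes are assigned with prevalences 68%
  classical, 10% non-classical, 3% GPI (the remainder none), and scores
  are drawn on the correct side of the rule thresholds; 70% of proteins
  carry an extracellular GO cell-component term.

Each artifact uses its own RNG stream derived from the master seed by a
fixed offset, so generating one artifact never shifts another, and a
fixed seed yields byte-identical files.

What the generator does **not** emulate: peptide-level quantification and
razor-peptide assignment, correlated missingness across replicates,
batch/run-order effects, protein–protein intensity correlation,
compositional coupling between samples, heterogeneous (non-uniform)
effect sizes, and atlas tissues with partially shared expression (e.g.
adipose-embedded glands). Passing tests therefore demonstrate algorithmic
correctness and calibration under the stated generative model, not
performance on any real dataset.

## Imputation

Missing log₂(LFQ) values are drawn per sample column from
N(μ − d·σ, (w·σ)²) with μ, σ the mean and SD (ddof = 1) of that column's
*observed* values, width w = 0.3 and downshift d = 1.8 — the standard
Perseus convention. Column-wise (rather than global) moments are used
because the width/downshift convention is defined relative to each
sample's distribution. Observed values are never altered; a column needs
at least two observed values, otherwise the stage raises. All draws come
from an explicit seed; there is no global RNG state.

## Permutation-FDR ANOVA

Per protein, the one-way ANOVA F across cell types is computed on the
imputed matrix. The null is built from `n_perm` (default 250) uniform
random permutations of the sample labels, the same permutation applied to
every protein within a randomization so protein–protein correlation is
preserved under the null. The q-value is the pooled-ratio (SAM/Tusher
style) estimator

    q(F) = [ mean over randomizations of #(F_perm ≥ F) pooled over proteins ]
           / #(F_obs ≥ F)

clipped to [0, 1] and monotonized with the canonical q-value convention
(q(F) = minimum of the raw estimate over all thresholds at or below F).
Constant rows have undefined F and are assigned q = 1. Ties in F share a
raw estimate by construction; remaining order follows input order.
Permutations are unstratified (the estimator's metadata records this);
significance defaults to q < 0.01.

**Small-design conservativeness.** With 3 groups × 3 replicates there are
only 1680 label assignments (280 distinct groupings), and a uniform
permutation reassembles any given replicate triplet into a single group
with probability 60/1680 ≈ 3.6%. Such permutations reproduce the observed
F exactly, so when many proteins carry large shared-design effects the
pooled permuted pool always contains a few super-threshold statistics per
randomization and q cannot fall below roughly 0.015–0.035 — *regardless*
of effect size. This is a structural property of label-permutation FDR at
n = 3 per group, not an implementation artifact: per-protein permutation
p-values are bounded below by 1/280 for the same reason. Consequently, on
synthetic data where most planted effects are large and share the design,
essentially nothing is certified at q < 0.01; the estimator remains
well-calibrated (conservative) on the global null. For small designs with
pervasive signal, a threshold of q < 0.05 or a parametric BH analysis is
the practical alternative; the threshold is a parameter everywhere.

## Moderated tissue differential expression

The atlas comparisons use a two-sample t with empirical-Bayes variance
moderation. Per gene, the pooled residual variance s² (df = n₁ + n₂ − 2)
is shrunk toward a prior: assuming s² ~ s₀²·F(df, d₀), the prior df d₀
and scale s₀² are estimated by method of moments on log s² (matching the
mean and variance of log s² to the log-F moments via digamma/trigamma;
the trigamma inverse is solved by Newton iteration). The posterior
variance (d₀s₀² + df·s²)/(d₀ + df) enters the t statistic with d₀ + df
degrees of freedom. When the observed spread of log s² does not exceed
the chi-square sampling spread, d₀ → ∞ and all variances collapse to the
pooled value; `prior_df=0` recovers the ordinary equal-variance t (tested
numerically). The implementation is validated against an independent
moderated-statistics fit in R on a shared fixture.

A comparison is significant when log₂FC (adipose minus tissue) > 4 and
the BH-adjusted p < 0.05, with BH applied across genes *within* each
tissue-pair comparison (mirroring per-contrast DE practice; applying it
across all T − 2 comparisons jointly is available by adjusting the
returned raw p-values). The fold-change criterion is one-sided in the
enrichment direction.

**Enrichment score.** score = 100 · n_enriched / (T − 2). The adipose
reference is a mode parameter: `"white"`, `"brown"`, `"combined"` (both
depots' replicates pooled; the default, matching the worked 76/86
example) or `"any"` (a tissue counts when significant against any of the
three references). The wording that motivated the mode is ambiguous
between these readings, so all are computed rather than one intent
guessed.

## Relative expression and t-SNE

Per-gene tissue profiles divide each tissue's mean expression by the sum
across tissues. Means are taken on the linear scale (2^log₂ averaged),
because the source atlas normalizations are linear; a flag switches to
log-scale means. Ties for the highest-expressing tissue break by tissue
name order. The t-SNE embedding (perplexity 30, 1000 iterations, PCA
initialization) is seeded and reproducible; embedding coordinates are
never asserted directly in tests — only invariant properties (duplicate
rows land close, planted orthogonal groups separate with silhouette
> 0.5).

## Clustering and overrepresentation

Rows are z-scored with population SD (a zero-variance row is an error
naming the protein). Clustering is agglomerative with complete linkage on
Euclidean distance of the z-rows (the linkage is the stated convention;
the metric is this package's choice, recorded in the assignment
metadata), cut to k = 4 by maxclust. Cluster labels are relabelled
deterministically — by descending cluster mean over a chosen sample group
(the pipeline uses the first cell type, so cluster 1 is the most
enriched there), or by first appearance in input order. Rows only are
clustered (no biclustering). The abundance ranking sorts by mean iBAQ
descending with a stable sort (input order breaks ties).

Per-cluster functional annotation uses a one-sided hypergeometric
overrepresentation test against the detected-protein background with BH
adjustment. This is an explicit, offline stand-in for web-based
annotation services; it makes no claim of reproducing any service's term
lists.

## Secretion rules

All inequalities are strict exactly as stated (> 0.5, > 0.6, > 99%; the
non-classical side condition is ≤ 0.5), so classical and non-classical
are mutually exclusive by construction — a property test over random
annotations asserts it. A missing predictor output contributes False
rather than raising, because real predictor tables have dropouts; a
completeness report summarizes per-field coverage. Localization matching
is case-insensitive exact equality with "extracellular".

## Candidate funnel

Evidence layers join on case-folded gene symbols (the analysis moves
between protein and gene spaces; a collision after normalization is an
error listing the colliding symbols). The report covers the union of all
inputs in alphabetical order; a gene without an enrichment score fails
the score criterion; the score threshold (default 80) is strict.

## Problem sizes and runtime

The validation suite uses deliberately desk-scale problems: 742-protein
CM matrices, a 300 × 88 × 3 atlas, 1000-protein × 250-permutation FDR
simulations (20 null repetitions), 100 brute-force linkage instances of
≤ 8 points, and 10,000-draw imputation moment checks. The full synthetic
pipeline runs in about two seconds on one CPU; the complete test suite in
well under a minute.

## Known limitations

* Real protein-groups tables can carry multi-accession groups and
  gene-name collisions that the synthetic namespace avoids; the candidate
  join surfaces collisions as errors rather than resolving them.
* The permutation-FDR estimator is conservative at small group sizes
  under pervasive signal (see above) and its q-resolution is limited by
  1/n_perm.
* The moderated-t prior is estimated without robustness against variance
  outliers and without covariate dependence of the prior.
* The overrepresentation test ignores annotation-term hierarchy and
  term–term correlation.
* Serum evidence is consumed as a detection set; serum-side quantitative
  modelling is out of scope.
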