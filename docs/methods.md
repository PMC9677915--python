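# Methods

This note records the statistical procedures, the defaults and their
rationale, the synthetic-data model, and the numerical choices made where
the design was genuinely open.

## Preprocessing

Counts are filtered (a gene is kept when it has ≥ `min_count` = 10 reads in
≥ `min_prop` = 20% of samples — common practice for bulk RNA-seq count
filtering), normalized by the trimmed mean of M-values (TMM), and reported
as log2(CPM + 0.5) on effective library sizes. The TMM reference sample is
the one whose 75th percentile of library-scaled counts is closest to the
mean 75th percentile; each sample's factor is the precision-weighted mean
of gene-wise log2 ratios after trimming 30% per tail of M-values and 5% per
tail of A-values, with factors normalized to unit geometric mean. The
implementation reproduces edgeR's `calcNormFactors(method="TMM")` to ≤ 1e-6
on integer count tables (cross-checked in the test suite) and is exactly
scale-invariant: multiplying a sample's counts by a constant leaves its
normalized column unchanged.

Per-gene z-scaling stores the scaling cohort's mean and sample SD
(ddof = 1) so external cohorts can either be re-scaled within themselves
(default) or projected onto a reference model (`reference=` /
`--reference`). Whether a study should project or re-scale external cohorts
is a genuine design choice — projection preserves the training scale but
imports cohort batch effects; re-scaling is the default here because the
downstream scores are relative statements within a cohort. Zero-variance
genes are dropped and reported.

## Differential expression

Per-gene two-group comparison with empirical-Bayes variance moderation:
gene-wise residual variances are shrunk toward a prior estimated by fitting
a scaled F distribution to the variance distribution (method of moments on
log variances, with the inverse-trigamma solved by Newton iteration). The
moderated t uses augmented degrees of freedom; with the prior forced to 0
degrees of freedom it reduces exactly to the classical pooled-variance
t-test (asserted in the tests). Significance is Benjamini-Hochberg adjusted
p < 0.05 with no fold-change floor. Correlated gene clusters use Spearman
correlation (p by the t approximation, BH over the upper triangle) and
average-linkage hierarchical clustering on 1 − ρ, cut at k = 4 by default.

## Risk signature

Candidate genes are the differentially expressed (core-)matrisome genes;
restricting the elastic net to this pool is part of the method, not an
optimization — selection over a genome-scale pool is not
selection-consistent at these sample sizes and admits dozens of false
selections (verified against R glmnet, which behaves the same way).

The elastic-net logistic path follows the glmnet convention: loss averaged
over samples plus λ·[α‖β‖₁ + (1−α)/2‖β‖₂²] with α = 0.5; 100 λ values
log-spaced over [λ_max·1e-4, λ_max], where λ_max is the smallest λ with all
coefficients zero; 10-fold stratified cross-validation; λ chosen by the
one-standard-error rule on the binomial deviance (misclassification rate is
available via `cv_metric="class"`; both were examined and select almost
identically here). The path is solved by iteratively reweighted least
squares with active-set cyclic coordinate descent and
Karush-Kuhn-Tucker screening (the glmnet algorithm), jit-compiled, and
validated coefficient-by-coefficient against scikit-learn's saga solver.

Signature weights are Firth-penalized logistic log-odds ratios fitted
jointly over the selected genes (a `per_gene` mode exists for comparison;
the joint fit is the default because the selected genes are correlated and
the score is a joint linear predictor). The Firth fit maximizes
log-likelihood + ½·log det I(β) by Newton iteration with step-halving,
gradient tolerance 1e-8, 200 iterations maximum; estimates are finite under
complete separation (asserted against a brute-force grid maximization).
Clinical covariates, when supplied, are appended to the joint design and
reported separately; gene selection is not re-run with covariates.

ROC AUC is the rank statistic with ties counted half (identical to the
trapezoidal integral of the empirical curve). Minimal-signature refinement
scores subsets by stratified-CV AUC of Firth refits — exhaustive when the
subset count is ≤ 1e5, greedy forward selection otherwise; ties break
toward smaller subsets, then lexicographic gene order. The refinement
procedure is this package's choice of a defensible search; it is not
claimed to reproduce any particular published subset.

## Matreotype discovery

Consensus clustering runs, for each K in 2..10 by default, 100 K-means
clusterings of random 80% sample subsets (single initialization per
resample; the consensus over resamples supplies the stability averaging);
consensus(i,j) is the co-clustering rate among co-subsampled draws. PAC is
the fraction of upper-triangle consensus entries strictly inside
(0.1, 0.9). The null model draws 25 reference datasets from a multivariate
normal with the real per-gene means and the gene covariance
eigenstructure (eigendecomposition of the sample covariance; a per-gene
permutation null is available via `null_mode="permute"`). Each reference is
processed identically; RCSI(K) = ln(mean null PAC) − ln(real PAC) with PAC
floored at 1e-4 before the logarithm, and the Monte-Carlo p-value is
add-one corrected, so at least 20 reference iterations are needed for
p < 0.05 to be attainable. The chosen K maximizes RCSI among K with
p < 0.05; when no K is significant the result says so rather than forcing
a clustering. Note the RCSI has published variants; the log-ratio form
above is the one this package computes and reports. Final labels come from
K-means with 25 restarts on the full data; non-tumor samples are clustered
together with tumors, and downstream survival contrasts use the tumor
clusters only.

Centroids are per-label means of z-scaled expression; assignment is
minimum Euclidean distance with ties to the first label in sorted order.
Canonical-subtype classification is the highest Pearson correlation with a
user-supplied centroid table over ≥ 10 shared genes; a negative best
correlation is flagged low-confidence.

## Outcome statistics

Kaplan–Meier, the k-group log-rank test, and Cox proportional hazards are
delegated to lifelines (Efron tie handling; Newton precision tightened to
1e-12 so that on tie-free data the fit matches an independent Breslow
implementation to 1e-8). Categorical groups are dummy-coded against a
reference level (first sorted label unless specified — ECM-Low in the
matreotype contrasts, so hazard ratios read as ECM-High vs ECM-Low). Stage
is ordinal-coded I=1..IV=4. Groups with zero events stay in the KM output
but drop from the log-rank test with the degrees of freedom reduced.

Fisher exact tests use the two-sided convention that sums hypergeometric
probabilities at most that of the observed table — the convention of
`fisher.test` in R and `scipy.stats.fisher_exact` — which matters for
reproducing published p-values; enrichment tables are per-category
(category vs rest × binary grouping). Mann-Whitney U tests are exact when
both groups have ≤ 8 samples and no ties, otherwise tie-corrected normal;
BH adjustment applies within each analysis family.

## Sample scores

The default single-sample gene-set score is a rank-based running-sum
enrichment statistic computed per sample: genes ordered by decreasing
expression; the in-set cumulative distribution weights genes by
rank^0.25; the statistic is the summed difference between in-set and
out-of-set cumulative distributions, normalized by its range across
samples. This is a per-sample enrichment score of the same contract as
kernel-density single-sample methods; outputs carry a `method` tag
(`rank_enrichment`, `weighted_z`, `module_score`) so the scorer is always
explicit. The fibrosis score is the signed sum of z-scaled expression over
a ±1-weighted signature (z-scaling chosen as the natural reading of
"normalized expression" for a signed sum; any per-gene standardization
only changes the score's scale). Per-cell module scores bin genes into 24
expression bins and subtract the mean of up to 100 expression-matched
control genes per set gene, seeded for reproducibility.

## Ligand–receptor interactions

Interaction scores are products of z-scaled ligand and receptor
expression. Because both factors are centered, co-depletion scores
positive; this is retained as the score's definition, with a
`truncate_negative` flag to zero-truncate z-values for consumers who want
co-enrichment only. Ligands are restricted to core-matrisome genes when an
annotation is supplied at load. Aggregation to receptor classes or
pathways takes the maximum over member pairs; group contrasts between
matreotypes reuse the moderated two-group machinery (class-aggregated
scores are the primary contrast unit).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, at
the scale of the cohorts it targets: 240 tumors vs 40 non-tumor samples,
2000 genes of which 300 are "matrisome", latent log2 expression with
per-gene SD 1 and equicorrelated gene blocks (default blocks of 30/25/20
genes at ρ = 0.7/0.6/0.5, realized as √ρ·shared + √(1−ρ)·own noise), 20
signature genes shifted ±1 SD in tumors (half up, half down), an ECM
program block additionally shifted in the ECM-High tumor subtype (60% of
tumors), negative-binomial counts (variance μ + 0.1·μ²) at library sizes
0.8–1.2 million, exponential survival with median 30 months and a planted
ECM-High log hazard ratio of ln 2, ~20% random censoring plus
administrative censoring at 120 months. One root seed spawns independent
substreams per stage so adding a stage never perturbs earlier draws. The
premalignant generator shifts a chosen risk-gene set toward the tumor
profile by a configurable fraction of the tumor effect in "progressive"
lesions.

What the generator does **not** emulate: batch effects, library-protocol
biases, gene-length effects, compositional coupling beyond library-size
normalization, non-proportional hazards, informative censoring, or
realistic matrisome co-expression topology. Passing recovery tests
therefore demonstrates that the pipeline's inference machinery is correct
and calibrated under its own assumptions — not that those assumptions hold
in any particular patient cohort.

## Problem sizes in the validation experiments

The recovery experiments run at the scale the analysis targets where that
is cheap (signature recovery: 10 cohorts of 2000 genes × 280 samples; Cox
recovery: 10 cohorts of 300 tumors per arm) and at reduced scale where the
full computation adds nothing to the check (consensus-clustering recovery:
5 datasets of 60 samples × 20 genes with 100 resamples and 25 Monte-Carlo
references per K, K = 2..6; the expression matrix for the Cox experiment
uses 120 genes since the survival machinery never touches expression).
Null-calibration checks use 20 cohorts of 2000 genes at 60 + 60 samples
for differential expression, 1000 label permutations for log-rank
uniformity, and 5 × 300 null interaction classes.

## Known limitations

- The consensus-clustering null preserves the gene covariance
  eigenstructure but not higher moments; heavy-tailed expression could
  make the Monte-Carlo p anti-conservative.
- The elastic-net path solver assumes standardized (z-scaled) inputs and
  does not re-standardize internally.
- `refine_minimal_signature` optimizes CV AUC, which plateaus early on
  strongly separable cohorts; reported subset rankings are then driven by
  the tie-break rules.
- Paired tumor/non-tumor designs are not modeled; the differential
  expression contrast is unpaired two-group.
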