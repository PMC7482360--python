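# Methods

This note documents the models and procedures implemented in `bloodgwas`,
the synthetic study conditions under which they are validated, the numerical
choices that were genuinely open, and what the passing test batteries do and
do not demonstrate about real data.

## Synthetic cohorts

**Genotypes.** Dosages are generated per LD block by mosaic copying from a
pool of 20 founder haplotypes: each sample haplotype starts on a random
founder and switches templates with probability 0.05 per site. Founder
alleles are thresholded latent AR(1) Gaussians (serial correlation 0.97), so
the founder pool itself carries LD that decays with distance; mosaic copying
propagates it to the population. At the default 25-variant block span this
yields mean adjacent-pair r² ≈ 0.4, a smooth decay to near-independence
across a block, occasional near-perfect proxy pairs (r² > 0.9), and exact
independence between blocks — the features the conditional-analysis and
fine-mapping stages are sensitive to. Target minor-allele frequencies are
uniform on a configurable range (default 0.05–0.5); because a 20-founder
pool can lose a low-frequency allele entirely, realized frequencies scatter
around the target and a small fraction of variants come out rare or
monomorphic, which downstream code must tolerate (the scan skips
monomorphic variants with a log entry). Two cohorts drawn with the same
`locus_seed` but different `seed` share the variant panel and LD structure
while sampling independent individuals — the construction used for
train/test splits. Imputation-style dosage uncertainty is simulated by
adding Gaussian noise to hard calls and recording INFO as the ratio of
observed to expected dosage variance, which gives the INFO ≤ 0.4 QC filter
something real to act on.

**Phenotypes.** A quantitative trait is the sum of (i) sparse large effects,
β per allele on stated causal variants; (ii) a dense polygenic background
built from standardized dosages with Gaussian weights, rescaled so its
realized variance is exactly the configured h²; (iii) covariate effects on
standardized age, age², sex and principal components (age ~ U(40, 70),
sex ~ Bernoulli(0.5), PCs ~ N(0, 1)); and (iv) Gaussian noise absorbing the
remaining budget so the total variance is ≈ 1. A budget exceeding 1 is an
error, not a silent rescale. Ground truth (effects, weights, components) is
retained for recovery tests. The recovery batteries size causal effects on
the z scale from the realized allele frequency (β = z/√(2p(1−p)n)) and remap
causal positions that landed on rare variants to the nearest common one
(EAF in [0.1, 0.9]), so the detection regime is a controlled condition
rather than a consequence of the frequency draw.

**Coexpression network.** The correlation matrix is the sample correlation
of a latent-factor expression model over `n_obs` (default 150) pseudo
samples, which makes it positive semi-definite by construction (a
nearest-PSD repair runs only defensively). Genes are partitioned into
modules of `base_degree + 1` members with within-module correlation 0.45;
core genes additionally load a shared core factor (inducing the configured
core–core correlation) and join extra modules in proportion to the degree
multiplier, with loadings scaled to the unit variance budget. At multiplier
1 and background-level core correlation a core gene is statistically
indistinguishable from a regular module member, which is the null
configuration the calibration tests rely on. The finite expression sample
size sets the background correlation level (≈ 1/√n_obs ≈ 0.08), standing in
for the estimation noise of a real whole-blood coexpression matrix.

**Trans-eQTL table.** Records are assigned to target genes with multinomial
weights of 1 for peripheral and `enrichment` for core genes, so the expected
per-gene count ratio equals the enrichment fold. Core genes also receive
modestly higher median expression (+0.5 SD), reproducing the
detection-power confounding that the matched enrichment test must remove.

**Disease labels.** Case status is drawn from a logistic model in the
standardized score with slope log(OR per SD); the intercept is calibrated by
root finding so the expected prevalence matches the target given the
empirical score distribution.

## Phenotype preparation

Extreme-measurement exclusions flag clinically implausible values
(WBC > 200×10⁹/L, HGB > 20 g/dL, HCT > 60%, PLT > 1000×10⁹/L); clinical and
medication exclusions are a pass-through boolean supplied by the user — the
package does not encode diagnosis-code logic. White-cell subtype counts are
the total count times the subtype proportion. Traits (log10-transformed for
the white-cell family) are regressed on covariates by OLS and the residuals
mapped to normal scores by the rank-based inverse-normal transform with the
Blom offset, z_i = Φ⁻¹((r_i − 3/8)/(n + 1/4)), ties receiving average ranks.
The offset and tie rule are conventions chosen here, not prescribed ones.
After the transform the output is re-standardized, so adjusted traits have
mean 0 and variance 1 to numerical precision (raw Blom scores have variance
slightly below 1 at finite n).

## Association and meta-analysis

The scan is per-variant OLS with two-sided t-tests (df = n − 2), vectorized
over variants via centered cross-products. A linear mixed model is the
field's standard at biobank scale to absorb relatedness; the synthetic
cohorts are unrelated by construction, so OLS is the exact special case and
is used throughout — a documented divergence from mixed-model pipelines.
Fixed-effects pooling uses inverse-variance weights after harmonizing every
cohort's effect allele (flipping β and EAF as needed); pooling one cohort is
the identity, and on split halves of one population the pooled estimate
agrees with individual-level OLS well within sampling error. Two
genome-wide thresholds are carried as named constants: 8.31×10⁻⁹ (the
conditional-analysis threshold) and 5×10⁻⁹ (the meta-analysis conditioning
step); both are configurable arguments.

## Exact stepwise conditional analysis

Blocks are formed by splitting the position-sorted significant variants at
every inter-variant gap ≥ 5 Mb — the reading that maximizes the number of
blocks, with the gap measured between nearest members — and any block over
2,500 variants is further split at its largest internal gaps (the cap is
stated upstream; the split rule is a choice made here). Within a block the
algorithm is: seed the model with the lowest-univariable-p variant; then
repeatedly (a) for each candidate not in high LD (r² > 0.9, computed from
the analysis samples themselves) with any model member, test its coefficient
when added, stopping when the best addition misses p < 8.31×10⁻⁹; (b) after
each addition, repeatedly drop the member with the largest drop-one p while
that p is at or above the threshold. The nested-model t test is implemented
as the coefficient t test of the added/dropped variant, which is equivalent
for one-variable nesting. Ties in the addition race break to the lower
genomic coordinate; all linear algebra runs on centered Gram matrices, and
rank-deficient joint models (perfect collinearity) fall back to the
pseudoinverse, whose inflated standard errors let the removal stage resolve
the redundancy deterministically. One guard departs from a literal reading:
if even the best univariable p misses the threshold the model is returned
empty — in the intended use blocks contain only genome-wide-significant
variants, so the guard is vacuous there, and it makes the null behaviour
(no selections on pure noise) correct when the function is applied to
unfiltered variant sets. The r² > 0.9 skip applies to addition only, as
stated. Convergence is guaranteed because every addition strictly decreases
the residual sum of squares and the model size is bounded; an iteration cap
raises rather than loops. Per chromosome, all block selections enter one
joint model and the algorithm resumes at the removal stage; since no
candidates exist outside the model at that point, refinement is the removal
loop followed by a final refit. LD clumping of sentinels is greedy by best
p: the top remaining sentinel tags a locus, sentinels with r² > 0.8 to the
tag join it, and by construction all between-tag r² ≤ 0.8.

## Fine-mapping

Regions are transitively merged ±250 kb sentinel windows; K per region is
its sentinel count. The configuration Bayes factor is the marginal
likelihood ratio of the standard summary-statistic Bayesian linear model,
z_γ ~ N(0, R_γγ + n·s²·R_γγR_γγ) against z_γ ~ N(0, R_γγ), with prior effect
SD s = 0.08 on standardized-dosage effects (so the z-scale prior variance is
n·s²), LD taken from the analysis samples, and Cholesky-based Gaussian
log-densities. Configurations with singular restricted LD (perfectly
correlated variants) are skipped with a log entry. Posteriors are exact
enumeration over all configurations of sizes 1..K — replacing stochastic
search, exact at the region sizes handled here, guarded at 2×10⁶
configurations — under a prior uniform over k and uniform within each k
(only K and s are prescribed upstream; the configuration prior is a choice
made here). PIP_v sums the posteriors of configurations containing v. The
95% credible set is grown greedily by descending PIP until the jointly
covered mass Σ_γ P(γ)·|γ∩S|/|γ| reaches 0.95; for K = 1 this coverage is
exactly the summed PIP. Ties in PIP break deterministically by index, and a
1e-12 boundary tolerance keeps exact-boundary cases (uniform PIPs) minimal;
per-signal (conditional) credible sets are out of scope and the region-level
reading is the one implemented. For K = 1 the posteriors equal normalized
Wakefield ABFs to ~1e-15 relative error, and the general formula is verified
against a Gauss–Hermite quadrature oracle on fixed 3-variant instances.

## Network test battery

Edges are |correlation| > cutoff — absolute value by choice, since negative
coexpression is not addressed by a one-sided cutoff rule. All permutation
p-values use the add-one estimator (1 + #{null ≥ observed})/(n_perm + 1),
which floors at 1/(n_perm + 1) and avoids p = 0. Degree comparisons and
effect-size comparisons use one- and two-sided Wilcoxon rank-sum tests; a
cutoff above every correlation yields a flagged degenerate result with
p = 1 rather than an error. Matching (for the MAF-matched effect-size
comparison and the trans-eQTL enrichment) is greedy nearest-neighbor
without replacement, processed in covariate order for determinism, with
rank-scaling to [0, 1] before Euclidean distance when matching on several
covariates; annotation classes with fewer than 10 variants per group are
skipped with a log entry. Trans-eQTL enrichment matches peripheral genes to
core genes on rank-inverse-normalized median expression and mean |Z| (genes
without records receive the overall mean |Z|), then compares per-gene
counts; the fold is the ratio of mean counts. Neighbor sets at graph
distance ≤ 2 are computed by boolean matrix products on the adjacency
matrix. In synthetic mode the permutation universe is the simulated gene
panel; real-data users must supply their own protein-coding universe.

## Polygenic scores

Weights are marginal (strategies a, b) or joint-model (c, d) betas oriented
so every stored weight is non-negative after allele flipping. LD pruning is
greedy by ascending p at r² > 0.8. Strategy b is evaluated at all four
thresholds {0.05, 5×10⁻⁴, 5×10⁻⁶, 5×10⁻⁸} as a comparison report; no
automatic pick is made unless a validation cohort is supplied. Scoring
mean-imputes model variants missing from the genotypes (a constant shift,
logged per variant, with no effect after standardization) and standardizes
the raw weighted sum; affine transforms of the raw score therefore leave R,
R² and OR per SD unchanged. Disease models are logistic regressions with
optional covariates, refused below 40 cases or on detected separation
(non-finite or explosive standard errors), with Bonferroni correction
across the supplied disease count. The carrier-penetrance odds ratio comes
from the 2×2 table cross-product with a Woolf CI and the Haldane–Anscombe
0.5 correction when a cell is zero (flagged); it equals the covariate-free
logistic OR to numerical precision. The PGS-deviation check flags carriers
with |score| > 2 SD of the population score and adds a logistic group test
when there are more than 10 carriers.

## Discovery saturation

All four growth forms are fit by ordinary least squares on their transformed
designs; selection is by AICc, a labeled choice (only "best fitting" is
stated upstream). With exactly four points the three-parameter √x + x form
has a divergent AICc correction and is never selected — the small-sample
guard that keeps the saturated form from winning trivially; with more
points it competes normally. Ties break to fewer parameters. Projections
evaluate the selected model at a new sample size and also report the
straight line through the first three points, the visual reference used
when judging whether the fourth point falls off the linear trend.

## Validation batteries and their problem sizes

The acceptance batteries run at: 50 three-causal recovery blocks and 500
null blocks of 200 variants at n = 5,000 (expected causal |z| = 9,
comfortably above the threshold's z ≈ 5.77); 200 single-causal fine-mapping
regions of 50 variants (expected |z| = 7); a 10,000-sample train/test pair
with 20 causal variants summing to 25% trait variance for the PGS battery;
20 disease cohorts of 20,000 samples at 5% prevalence and OR 1.5/SD;
400-gene networks with 20 core genes (degree multiplier 5, core correlation
0.3, eQTL enrichment 2) against 200 random-label calibration runs; 30-seed
matched fold-change batteries; and 100 noisy replicates per saturation
form at noise σ = 2% of range. The whole battery completes in about a
minute on one CPU.

## What passing does and does not show

The generators reproduce the statistical structure the methods assume —
block LD, sparse-plus-polygenic architecture, hub-structured coexpression,
enrichment with power confounding, logistic disease risk — but not the
full texture of real data: no relatedness or population structure (the
reason OLS substitutes exactly for the mixed model here), no imputation
panel or X chromosome, no coalescent allele-frequency spectrum, no
cohort-specific covariates, and a coexpression matrix whose background is
pure sampling noise rather than shared technical variation. Recovery and
calibration results therefore validate the implementations under their own
stated assumptions; they are not estimates of performance on any real
cohort, and the real-data headline numbers of biobank-scale studies are not
reproducible at these problem sizes.

## Known limitations

Exhaustive enumeration bounds fine-mapping regions to desk scale (the guard
refuses > 2×10⁶ configurations); summary-statistic conditional analysis
(GCTA-COJO-style) is not implemented — conditioning requires individual
level data here; heterogeneity statistics (Cochran's Q, I²) are not
computed in the meta step; LD-aware shrinkage scores are out of scope for
the PGS module; and the penetrance machinery assumes a single dichotomizing
bound per trait.
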