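# bloodgwas

A statistical-genetics toolkit for blood-trait GWAS downstream analysis:
exact stepwise conditional analysis, Bayesian fine-mapping with 95% credible
sets, an omnigenic-model network test battery, polygenic scores and their
disease associations, and discovery-saturation modeling — all exercised on
seeded synthetic cohorts, so the full pipeline runs and is testable without
access to any biobank data.

## Who this is for

Hematological traits (platelet count, hemoglobin, white-cell subtype counts,
…) are a standard proving ground for complex-trait genetics: they are
measured in every large cohort and their production is governed by a
well-characterized regulatory hierarchy. The computations that turn a
genome-wide scan of such traits into biology — picking apart a significant
region into conditionally independent signals, assigning posterior causal
probabilities to variants, asking whether Mendelian "core" genes sit at the
center of coexpression networks, converting thousands of small effects into
a predictive score — are usually re-implemented ad hoc per study. This
package provides them as a tested, reusable library with a thin CLI.

## The methods at its core

**Association and meta-analysis.** Per-variant OLS of the covariate-adjusted,
rank-inverse-normalized trait on allele dosage (on unrelated samples the
mixed model reduces to OLS); inverse-variance-weighted fixed-effects pooling
with w_i = 1/SE_i², β̂ = Σw_iβ_i/Σw_i, SE = (Σw_i)^(−1/2). Variant IDs are
harmonized as `chrom:pos_A1_A2` with deterministic allele ordering; QC
removes INFO ≤ 0.4 and MAC ≤ 5 (≤ 20 for very large cohorts).

**Exact conditional analysis.** Genome-wide-significant variants are
partitioned into blocks separated by ≥ 5 Mb (≤ 2,500 variants per block);
within each block a stepwise multiple regression alternates addition and
removal of variants at a t-test threshold of p < 8.31×10⁻⁹, skipping
candidates in LD r² > 0.9 with the model; per chromosome, all block
selections are refit jointly and pruned (the algorithm resumed at its
removal stage). Sentinels are clumped into loci at between-tag r² ≤ 0.8.

**Fine-mapping.** Regions are merged ±250 kb windows around sentinels, with
the maximum causal count K equal to the number of sentinels. For a causal
configuration γ the evidence is

  log BF(γ) = log N(z_γ; 0, R_γγ + n·s²·R_γγR_γγ) − log N(z_γ; 0, R_γγ),

with prior effect-size SD s = 0.08; posteriors come from exact enumeration
of all configurations of size 1..K, giving per-variant posterior inclusion
probabilities (PIPs) and minimal 95% credible sets. For one variant this is
the Wakefield approximate Bayes factor.

**Omnigenic-model tests.** Permutation overlap enrichment (fold enrichment
FE = observed/null mean, add-one p), Wilcoxon degree tests at hard
|correlation| cutoffs, a core-gene mutual-coexpression permutation test,
MAF-matched effect-size fold changes, trans-eQTL target enrichment after
matching on expression level and |Z|, and first/second-degree neighbor
enrichment.

**Polygenic scores.** Four selection strategies (LD-pruned genome-wide,
pruned + p-threshold, sentinels + PIP > 0.5, sentinels), weights oriented to
trait-increasing alleles, standardized weighted dosage sums, Pearson R / R²,
logistic disease models (OR per SD, ≥ 40 cases required), carrier-penetrance
odds ratios (Woolf CI, Haldane–Anscombe correction), and the PGS-deviation
check for rare-variant carriers.

**Discovery saturation.** Least-squares fits of y = a+bx, a+b√x, a+b√x+cx,
a+b·log x to (cohort size, discovery yield) points, selected by AICc.

## Worked example

```python
import bloodgwas as bg
from bloodgwas import workflows as wf, finemap as fm, pgs

# discovery cohort: 5,000 samples, 200 variants in LD blocks, 3 causal signals
cohort = wf.simulate_sparse_cohort(
    5000, 200, causal_positions=[10, 85, 160], target_z=9.0,
    seed=42, locus_seed=42,
)
res = wf.conditional_analysis(cohort.G, cohort.phenotype.values)
print(res.sentinels[["variant_id", "beta", "se", "p"]])

regions = fm.define_regions(res.sentinels)
fmres = wf.finemap_region(cohort.G, res.scan, regions[0], n=5000)
print(fmres.pip.max(), len(fmres.credible_set))

model = pgs.select_variants(res.scan, "d", sentinels=res.sentinels)
score = pgs.compute_pgs(cohort.G, model)
print(pgs.evaluate_pgs(score, cohort.phenotype.values))
```

This prints:

```
   variant_id      beta       se            p
1:1425000_A_T -0.192070 0.019617 1.952680e-22
1:1055000_A_T  0.179986 0.019539 4.625686e-20
1:1795000_A_G  0.196293 0.021410 6.872794e-20
```

— the stepwise model recovers exactly the three planted causal signals with
joint effects within sampling error of the simulated ±0.18–0.20 SD/allele.
The three sentinel windows merge into one region (K = 3) whose top PIP is
1.000 and whose 95% credible set holds 3 variants (one per signal), and the
3-variant sentinel score explains R² = 0.050 of the trait — matching the
planted per-signal variance of ~1.7% each.

A CLI mirrors the shell-facing steps:

```bash
bloodgwas simulate --n-samples 5000 --n-variants 200 --seed 1 --out run/
bloodgwas scan --vcf run/genotypes.vcf --pheno run/phenotypes.tsv --out stats.tsv
bloodgwas qc --stats stats.tsv --out stats.qc.tsv
bloodgwas meta stats.qc.tsv other_cohort.tsv --out pooled.tsv
bloodgwas saturation-fit --points discovery_counts.tsv
```

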