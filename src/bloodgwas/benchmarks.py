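"""Replication batteries: recovery, calibration, and power experiments.

Each function rebuilds its synthetic study conditions from a base seed and
measures one headline property of the pipeline: stepwise-selection recovery
and type-I control, fine-mapping credible-set coverage and the Wakefield
equivalence, meta-analysis agreement with pooled individual-level OLS, the
network test battery's null calibration and power, matched effect-size fold
changes, polygenic-score accuracy and disease odds ratios, and
saturation-model selection.  The same batteries back the acceptance tests
and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc, conditional, finemap, network, pgs, saturation
from .simulate import (
    GenotypeMatrix,
    NetworkSimConfig,
    SimConfig,
    simulate_disease,
    simulate_genotypes,
    simulate_network,
    simulate_phenotype,
    simulate_trans_eqtls,
)
from .workflows import conditional_analysis, simulate_sparse_cohort

# study conditions of the recovery/calibration batteries
N_BLOCK = 5000
M_BLOCK = 200
TARGET_Z = 9.0


def bonferroni_values() -> dict[str, float]:
    """The two analytic multiple-testing thresholds."""
    return {
        "phewas": assoc.bonferroni_threshold(0.05, 529),
        "celltype_by_trait": assoc.bonferroni_threshold(0.05, 18 * 22),
    }


def stepwise_recovery(n_rep: int = 50, seed: int = 0) -> float:
    """Fraction of replicates recovering all 3 causal variants (r^2 > 0.9
    proxies allowed) on blocks of 200 variants, n=5,000."""
    ok = 0
    for i in range(n_rep):
        c = simulate_sparse_cohort(
            N_BLOCK, M_BLOCK, [10, 85, 160], target_z=TARGET_Z,
            seed=seed * 100_003 + i,
        )
        res = conditional_analysis(c.G, c.phenotype.values)
        r2 = c.G.ld_r2()
        ok += all(
            any(s == t or r2[t, s] > 0.9 for s in res.selected_columns)
            for t in c.causal_indices
        )
    return ok / n_rep


def stepwise_null_rate(n_blocks: int = 500, seed: int = 0) -> float:
    """Fraction of pure-noise blocks with at least one false selection."""
    n_false = 0
    for i in range(n_blocks):
        cfg = SimConfig(
            n_samples=N_BLOCK, n_variants=M_BLOCK, ld_block_span=25,
            seed=seed * 99_991 + i,
        )
        G = simulate_genotypes(cfg)
        pheno = simulate_phenotype(G, cfg)
        res = conditional.stepwise_select(G, pheno.values)
        n_false += len(res.selected) > 0
    return n_false / n_blocks


def finemap_k1_equivalence(seed: int = 0, m: int = 30) -> float:
    """Max relative error between K=1 enumeration posteriors and the
    normalized closed-form Wakefield ABFs."""
    rng = np.random.default_rng(seed)
    z = rng.normal(0, 2.5, size=m)
    res = finemap.enumerate_posteriors(z, np.eye(m), K=1, n=N_BLOCK)
    labf = np.array([finemap.wakefield_log_abf(v, n=N_BLOCK) for v in z])
    expected = np.exp(labf - labf.max())
    expected /= expected.sum()
    return float(np.max(np.abs(res.posterior - expected) / expected))


def finemap_coverage(n_regions: int = 200, seed: int = 0) -> float:
    """Fraction of single-causal regions (m=50, n=5,000) whose 95% credible
    set contains the true causal variant."""
    cover = 0
    for i in range(n_regions):
        c = simulate_sparse_cohort(
            N_BLOCK, 50, [25], target_z=7.0, seed=seed * 60_013 + i
        )
        scan = assoc.single_variant_scan(c.G, c.phenotype.values)
        ids = scan["variant_id"].tolist()
        col_of = {v: j for j, v in enumerate(c.G.variants["variant_id"])}
        cols = [col_of[v] for v in ids]
        gstd = GenotypeMatrix(
            c.G.dosages[:, cols], c.G.variants.iloc[cols].reset_index(drop=True)
        ).standardized()
        R = (gstd.T @ gstd) / gstd.shape[0]
        z = (scan["beta"] / scan["se"]).to_numpy()
        res = finemap.enumerate_posteriors(z, R, K=1, n=N_BLOCK, variant_ids=ids)
        cid = c.G.variants["variant_id"].iloc[c.causal_indices[0]]
        cover += cid in res.credible_set
    return cover / n_regions


def meta_equal_weight_se() -> float:
    """Pooled SE of two unit-SE cohorts (closed form: 1/sqrt(2))."""
    row = pd.DataFrame(
        {"variant_id": ["v"], "chrom": ["1"], "pos": [1],
         "effect_allele": ["A"], "other_allele": ["G"], "eaf": [0.3],
         "beta": [1.0], "se": [1.0], "n": [1000]}
    )
    pooled = assoc.meta_fixed_effects([row, row.copy()])
    return float(pooled["se"].iloc[0])


def meta_vs_pooled_ols(seed: int = 0) -> float:
    """Max |IVW beta - pooled-OLS beta| / SE over split synthetic cohorts."""
    c = simulate_sparse_cohort(
        6000, 60, [10, 40], target_z=8, seed=seed + 17, locus_seed=seed + 17
    )
    half = c.G.n_samples // 2
    y = c.phenotype.values
    g1 = GenotypeMatrix(c.G.dosages[:half], c.G.variants.copy())
    g2 = GenotypeMatrix(c.G.dosages[half:], c.G.variants.copy())
    pooled = assoc.meta_fixed_effects(
        [assoc.single_variant_scan(g1, y[:half]),
         assoc.single_variant_scan(g2, y[half:])]
    ).set_index("variant_id")
    joint = assoc.single_variant_scan(c.G, y).set_index("variant_id")
    common = pooled.index.intersection(joint.index)
    dz = (pooled.loc[common, "beta"] - joint.loc[common, "beta"]).abs()
    return float((dz / joint.loc[common, "se"]).max())


def network_null_calibration(
    n_runs: int = 200, seed: int = 0
) -> tuple[float, float]:
    """Mean fold enrichment and KS uniformity p of permutation p-values for
    random query sets (labels carry no signal)."""
    rng = np.random.default_rng(seed)
    universe = [f"g{i}" for i in range(2000)]
    annotated = set(rng.choice(universe, 800, replace=False))
    ps, fes = [], []
    for i in range(n_runs):
        q = set(
            np.random.default_rng(seed * 7919 + i).choice(
                universe, 400, replace=False
            )
        )
        r = network.overlap_enrichment(
            q, annotated, universe, n_perm=500, seed=seed * 104_729 + i
        )
        ps.append(r.p)
        fes.append(r.fold_enrichment)
    return float(np.mean(fes)), float(stats.kstest(ps, "uniform").pvalue)


def network_power(seed: int = 0, n_seeds: int = 10) -> dict[str, float]:
    """Degree, coexpression, and trans-eQTL tests on the enriched generator
    (degree multiplier 5, core correlation 0.3, eQTL enrichment 2)."""
    folds, degree_ps, coexpr_ps, trans_ps = [], [], [], []
    for i in range(n_seeds):
        s = seed * 31_337 + i
        net = simulate_network(
            NetworkSimConfig(
                n_genes=400, n_core=20, base_degree=5,
                core_degree_multiplier=5, core_mutual_correlation=0.3, seed=s,
            )
        )
        core = set(net.core_genes)
        degree_ps.append(network.degree_test(net, core, 0.25).p)
        coexpr_ps.append(
            network.core_coexpression_test(net, core, n_perm=2000, seed=s).p
        )
        eq = simulate_trans_eqtls(net, 2.0, 5000, seed=s)
        te = network.trans_eqtl_enrichment(eq, core, seed=s)
        trans_ps.append(te.p)
        folds.append(te.fold)
    return {
        "degree_p": float(np.median(degree_ps)),
        "coexpression_p": float(np.median(coexpr_ps)),
        "trans_eqtl_p": float(np.median(trans_ps)),
        "trans_eqtl_fold": float(np.mean(folds)),
    }


def effect_matching_fold(
    boost: float, n_seeds: int = 30, seed: int = 0
) -> float:
    """Mean MAF-matched fold change when core-gene |beta| is ``boost``-fold
    the background at matched frequency."""
    fcs = []
    for i in range(n_seeds):
        rng = np.random.default_rng(seed * 15_485_863 + i)
        n = 400
        maf = rng.uniform(0.01, 0.5, n)
        core = rng.random(n) < 0.25
        beta = np.abs(rng.normal(0.05, 0.02, n)) * np.where(core, boost, 1.0)
        df = pd.DataFrame(
            {"abs_beta": beta, "maf": maf,
             "annotation_class": "coding", "core": core}
        )
        res = network.matched_effect_comparison(df, seed=i)
        fcs.append(res.per_class["fold_change"].iloc[0])
    return float(np.mean(fcs))


def _pgs_models(seed: int):
    """Train the sentinel and threshold strategies on one sparse cohort."""
    n_caus = 20
    pos = list(range(5, 800, 40))[:n_caus]
    c = simulate_sparse_cohort(
        10_000, 800, pos, variance_per_causal=0.25 / n_caus,
        seed=seed + 1, locus_seed=seed + 7_001,
    )
    res = conditional_analysis(c.G, c.phenotype.values)
    model_d = pgs.select_variants(res.scan, "d", sentinels=res.sentinels)
    model_b = pgs.select_variants(
        res.scan, "b", G_ref=c.G, p_threshold=5e-8
    )
    return c, model_d, model_b


def pgs_r2_recovery(seed: int = 0) -> dict[str, float]:
    """Held-out variance explained of the sentinel score against the
    generator's 0.25 target, plus the strategy comparison margin."""
    c, model_d, model_b = _pgs_models(seed)
    cfg = SimConfig(
        n_samples=10_000, n_variants=800, ld_block_span=25,
        causal_spec=list(zip(c.causal_indices, c.causal_betas)),
        seed=seed + 2, locus_seed=seed + 7_001,
    )
    Gt = simulate_genotypes(cfg)
    pht = simulate_phenotype(Gt, cfg)
    _, r2_d = pgs.evaluate_pgs(pgs.compute_pgs(Gt, model_d), pht.values)
    _, r2_b = pgs.evaluate_pgs(pgs.compute_pgs(Gt, model_b), pht.values)
    return {"r2_sentinels": float(r2_d), "r2_threshold_5e8": float(r2_b)}


def pgs_disease_or(n_seeds: int = 20, seed: int = 0) -> dict[str, float]:
    """Recovery of a 1.5-per-SD disease odds ratio at 5% prevalence,
    n=20,000 (fraction of seeds inside [1.35, 1.67] and the median OR)."""
    ors = []
    for i in range(n_seeds):
        s = seed * 224_737 + i
        score = np.random.default_rng(s).normal(size=20_000)
        dis = simulate_disease(score, 1.5, 0.05, seed=s + 1)
        ors.append(pgs.pgs_disease_association(score, dis.labels).or_per_sd)
    ors = np.array(ors)
    return {
        "fraction_in_band": float(np.mean((ors >= 1.35) & (ors <= 1.67))),
        "median_or": float(np.median(ors)),
    }


def saturation_selection(n_rep: int = 100, seed: int = 0) -> dict[str, float]:
    """Noiseless residual and noisy selection consistency for the growth
    forms on four cohort sizes."""
    x = np.array([35_000.0, 43_500.0, 83_000.0, 400_000.0])
    fit = saturation.fit_saturation_models(x, 3.0 * np.sqrt(x))
    noiseless = float(
        np.max(np.abs(fit.predict("sqrt", x) - 3.0 * np.sqrt(x)))
    )
    gens = {
        "linear": 2e-3 * x,
        "sqrt": 5.0 * np.sqrt(x),
        "log": 300.0 * np.log(x),
    }
    rates = {}
    for form, y0 in gens.items():
        hits = 0
        for i in range(n_rep):
            rng = np.random.default_rng(seed * 32_452_843 + i)
            y = y0 + rng.normal(0, 0.02 * np.ptp(y0), 4)
            sel = saturation.fit_saturation_models(x, y).selected
            hits += sel in (form, "sqrt+linear")
        rates[form] = hits / n_rep
    return {
        "noiseless_max_residual": noiseless,
        "min_selection_rate": float(min(rates.values())),
        **{f"rate_{k}": float(v) for k, v in rates.items()},
    }
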