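"""Polygenic scores: selection strategies, scoring, evaluation, disease."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bloodgwas as bg
from bloodgwas import pgs
from bloodgwas import workflows as wf


@pytest.fixture(scope="module")
def trained():
    """Training cohort with sparse architecture and its discovery outputs."""
    pos = list(range(5, 400, 40))
    c = wf.simulate_sparse_cohort(
        6000, 400, pos, variance_per_causal=0.02, seed=21, locus_seed=55
    )
    res = wf.conditional_analysis(c.G, c.phenotype.values)
    return c, res


class TestSelectVariants:
    def test_strategy_d_passes_sentinels_through(self, trained):
        c, res = trained
        model = pgs.select_variants(res.scan, "d", sentinels=res.sentinels)
        assert model.n_variants == len(res.sentinels)
        assert (model.weights["weight"] >= 0).all()

    def test_strategy_b_empty_selection_errors(self, trained):
        c, res = trained
        with pytest.raises(ValueError, match="no variants selected"):
            pgs.select_variants(res.scan, "b", G_ref=c.G, p_threshold=1e-300)

    def test_strategy_a_prunes_correlated_variants(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(800, 1)).astype(float)
        G = bg.GenotypeMatrix(
            np.column_stack([g, g]),
            pd.DataFrame({"variant_id": ["a", "b"], "chrom": "1",
                          "pos": [1, 2], "effect_allele": ["A", "A"],
                          "other_allele": ["G", "G"],
                          "eaf": [0.5, 0.5], "info": [1.0, 1.0]}),
        )
        stats_df = pd.DataFrame(
            {"variant_id": ["a", "b"], "chrom": "1", "pos": [1, 2],
             "effect_allele": ["A", "A"], "other_allele": ["G", "G"],
             "eaf": [0.5, 0.5], "info": [1.0, 1.0],
             "beta": [0.1, 0.1], "se": [0.01, 0.01],
             "p": [1e-10, 1e-9], "n": [800, 800]}
        )
        model = pgs.select_variants(stats_df, "a", G_ref=G)
        assert model.n_variants == 1
        assert model.weights["variant_id"].iloc[0] == "a"  # smaller p kept

    def test_strategy_c_adds_finemapped_variants(self, trained):
        c, res = trained
        fmtab = pd.DataFrame(
            {"variant_id": [res.scan["variant_id"].iloc[0]], "pip": [0.9]}
        )
        model_d = pgs.select_variants(res.scan, "d", sentinels=res.sentinels)
        model_c = pgs.select_variants(
            res.scan, "c", sentinels=res.sentinels, finemap_tables=[fmtab]
        )
        extra = set(model_c.weights["variant_id"]) - set(model_d.weights["variant_id"])
        assert model_c.n_variants >= model_d.n_variants

    def test_unknown_strategy_rejected(self, trained):
        _, res = trained
        with pytest.raises(ValueError, match="unknown strategy"):
            pgs.select_variants(res.scan, "z")


class TestComputePgs:
    def test_single_variant_score_is_dosage_transform(self, trained):
        c, _ = trained
        v = c.G.variants.iloc[5]
        model = pgs.PgsModel(
            weights=pd.DataFrame(
                {"variant_id": [v["variant_id"]],
                 "effect_allele": [v["effect_allele"]],
                 "other_allele": [v["other_allele"]], "weight": [1.0]}
            ),
            strategy="d",
        )
        score = pgs.compute_pgs(c.G, model)
        assert np.corrcoef(score, c.G.dosages[:, 5])[0, 1] == pytest.approx(1.0)

    def test_allele_flip_invariance(self, trained):
        c, _ = trained
        v = c.G.variants.iloc[5]
        w1 = pd.DataFrame(
            {"variant_id": [v["variant_id"]],
             "effect_allele": [v["effect_allele"]],
             "other_allele": [v["other_allele"]], "weight": [0.3]}
        )
        w2 = w1.assign(
            effect_allele=[v["other_allele"]], other_allele=[v["effect_allele"]]
        )
        s1 = pgs.compute_pgs(c.G, pgs.PgsModel(weights=w1, strategy="d"))
        s2 = pgs.compute_pgs(c.G, pgs.PgsModel(weights=w2, strategy="d"))
        assert np.allclose(s1, -s2)

    def test_zero_weights_rejected(self, trained):
        c, _ = trained
        v = c.G.variants.iloc[5]
        model = pgs.PgsModel(
            weights=pd.DataFrame(
                {"variant_id": [v["variant_id"]],
                 "effect_allele": [v["effect_allele"]],
                 "other_allele": [v["other_allele"]], "weight": [0.0]}
            ),
            strategy="d",
        )
        with pytest.raises(ValueError, match="zero score variance"):
            pgs.compute_pgs(c.G, model)

    def test_duplicate_variants_rejected(self):
        w = pd.DataFrame(
            {"variant_id": ["a", "a"], "effect_allele": ["A", "A"],
             "other_allele": ["G", "G"], "weight": [0.1, 0.2]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            pgs.PgsModel(weights=w, strategy="d")


class TestEvaluatePgs:
    def test_identity_gives_unit_r2(self, rng):
        x = rng.normal(size=100)
        r, r2 = pgs.evaluate_pgs(x, x)
        assert (r, r2) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_independent_vectors_near_zero(self):
        hits = 0
        for s in range(50):
            g = np.random.default_rng(s)
            r, _ = pgs.evaluate_pgs(g.normal(size=10_000), g.normal(size=10_000))
            hits += abs(r) < 0.05
        assert hits >= 49

    def test_r2_recovery_on_held_out_cohort(self, trained):
        c, res = trained
        model = pgs.select_variants(res.scan, "d", sentinels=res.sentinels)
        cfg = bg.SimConfig(
            n_samples=6000, n_variants=400, ld_block_span=25,
            causal_spec=list(zip(c.causal_indices, c.causal_betas)),
            seed=22, locus_seed=55,
        )
        Gt = bg.simulate_genotypes(cfg)
        pht = bg.simulate_phenotype(Gt, cfg)
        _, r2 = pgs.evaluate_pgs(pgs.compute_pgs(Gt, model), pht.values)
        target = sum(
            b**2 * 2 * p * (1 - p)
            for b, p in zip(
                c.causal_betas, c.G.variants["eaf"].iloc[c.causal_indices]
            )
        )
        assert abs(r2 - target) < 0.06

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pgs.evaluate_pgs(np.ones(10), np.arange(10.0))


class TestDiseaseAssociation:
    def test_or_recovered_within_band(self):
        score = np.random.default_rng(7).normal(size=20_000)
        dis = bg.simulate_disease(score, 1.5, 0.05, seed=7)
        res = pgs.pgs_disease_association(score, dis.labels)
        assert 1.35 < res.or_per_sd < 1.67
        assert res.ci_low < 1.5 < res.ci_high

    def test_null_ci_covers_one(self):
        covered = 0
        for s in range(30):
            score = np.random.default_rng(s).normal(size=8000)
            dis = bg.simulate_disease(score, 1.0, 0.08, seed=s)
            res = pgs.pgs_disease_association(score, dis.labels)
            covered += res.ci_low <= 1.0 <= res.ci_high
        assert covered >= 25

    def test_too_few_cases_refused(self, rng):
        score = rng.normal(size=1000)
        labels = np.zeros(1000, dtype=int)
        labels[:39] = 1
        with pytest.raises(ValueError, match="cases"):
            pgs.pgs_disease_association(score, labels)

    def test_separation_refused(self):
        score = np.linspace(-3, 3, 200)
        labels = (score > 0).astype(int)
        with pytest.raises(ValueError):
            pgs.pgs_disease_association(score, labels, min_cases=10)

    def test_bonferroni_across_diseases(self):
        score = np.random.default_rng(9).normal(size=20_000)
        dis = bg.simulate_disease(score, 1.3, 0.05, seed=9)
        res = pgs.pgs_disease_association(score, dis.labels, n_diseases=49)
        assert res.p_bonferroni == pytest.approx(min(1.0, res.p * 49))


class TestCarrierPenetrance:
    def test_cross_product_closed_form(self):
        carrier = np.repeat([True, False], [100, 200])
        trait = np.concatenate(
            [np.r_[np.zeros(10), np.ones(90)], np.r_[np.zeros(5), np.ones(195)]]
        )
        res = pgs.carrier_penetrance(carrier, trait, 0.5, direction="below")
        assert res.odds_ratio == pytest.approx((10 * 195) / (90 * 5))
        assert not res.corrected

    def test_zero_cell_haldane_correction(self):
        carrier = np.repeat([True, False], [10, 100])
        trait = np.concatenate([np.ones(10), np.r_[np.zeros(5), np.ones(95)]])
        res = pgs.carrier_penetrance(carrier, trait, 0.5)
        assert np.isfinite(res.odds_ratio) and res.corrected

    def test_null_ci_covers_one(self, rng):
        carrier = rng.random(2000) < 0.2
        trait = rng.normal(160, 20, 2000)
        res = pgs.carrier_penetrance(carrier, trait, 150.0)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_matches_logistic_regression_or(self, rng):
        import statsmodels.api as sm

        carrier = rng.random(3000) < 0.3
        trait = rng.normal(155, 15, 3000) - 5 * carrier
        res = pgs.carrier_penetrance(carrier, trait, 150.0)
        outside = (trait < 150).astype(int)
        fit = sm.Logit(outside, sm.add_constant(carrier.astype(float))).fit(disp=False)
        assert res.odds_ratio == pytest.approx(np.exp(fit.params[1]), abs=1e-6)

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            pgs.carrier_penetrance(np.ones(10, bool), rng.normal(size=10), 0.0)


class TestDeviationCheck:
    def test_population_carriers_flag_rate_near_tail_mass(self):
        g = np.random.default_rng(3)
        pop = g.normal(size=200_000)
        res = pgs.pgs_deviation_check(pop[:100_000], pop)
        assert res.flag_rate == pytest.approx(2 * stats.norm.sf(2), abs=0.005)

    def test_extreme_carrier_flagged(self, rng):
        res = pgs.pgs_deviation_check(np.array([3.0]), rng.normal(size=5000))
        assert res.flags[0] and res.branch == "threshold"

    @pytest.mark.parametrize("n_carriers,branch", [(11, "logistic"), (9, "threshold")])
    def test_group_test_branch_by_carrier_count(self, rng, n_carriers, branch):
        res = pgs.pgs_deviation_check(
            rng.normal(size=n_carriers), rng.normal(size=3000)
        )
        assert res.branch == branch
        assert (res.group_p is not None) == (branch == "logistic")

    def test_empty_carriers_rejected(self, rng):
        with pytest.raises(ValueError):
            pgs.pgs_deviation_check(np.array([]), rng.normal(size=100))


class TestStrategyComparison:
    def test_sentinel_strategy_at_least_matches_liberal_threshold(self, trained):
        """Sparse architecture: the sentinel-based score explains at least
        as much held-out variance as the pruned 5e-8-threshold score
        (within a small margin)."""
        c, res = trained
        model_d = pgs.select_variants(res.scan, "d", sentinels=res.sentinels)
        model_b = pgs.select_variants(res.scan, "b", G_ref=c.G, p_threshold=5e-8)
        cfg = bg.SimConfig(
            n_samples=6000, n_variants=400, ld_block_span=25,
            causal_spec=list(zip(c.causal_indices, c.causal_betas)),
            seed=23, locus_seed=55,
        )
        Gt = bg.simulate_genotypes(cfg)
        pht = bg.simulate_phenotype(Gt, cfg)
        _, r2_d = pgs.evaluate_pgs(pgs.compute_pgs(Gt, model_d), pht.values)
        _, r2_b = pgs.evaluate_pgs(pgs.compute_pgs(Gt, model_b), pht.values)
        assert r2_d >= r2_b - 0.02

    def test_affine_score_transform_leaves_metrics_unchanged(self, trained):
        c, res = trained
        model = pgs.select_variants(res.scan, "d", sentinels=res.sentinels)
        score = pgs.compute_pgs(c.G, model)
        r1, _ = pgs.evaluate_pgs(score, c.phenotype.values)
        r2, _ = pgs.evaluate_pgs(3.0 * score + 5.0, c.phenotype.values)
        assert r1 == pytest.approx(r2)
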