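"""Omnigenic test battery: enrichments, degree/coexpression tests, matching."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bloodgwas as bg
from bloodgwas import network as nw


@pytest.fixture(scope="module")
def universe():
    return [f"g{i}" for i in range(1000)]


class TestOverlapEnrichment:
    def test_saturated_annotation_gives_unit_fold(self, universe):
        res = nw.overlap_enrichment(
            set(universe[:50]), set(universe), universe, n_perm=200, seed=0
        )
        assert res.fold_enrichment == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_fully_annotated_query_matches_hypergeometric_fold(self, universe):
        annotated = set(universe[:100])
        query = set(universe[:50])  # drawn entirely from the annotated set
        res = nw.overlap_enrichment(query, annotated, universe, n_perm=2000, seed=1)
        # null mean = |query| * |annotated| / |universe| = 5 -> FE ~ 10
        assert res.fold_enrichment == pytest.approx(10.0, rel=0.1)
        assert res.p == pytest.approx(1 / 2001)

    def test_null_pvalues_uniform_across_seeds(self, universe):
        annotated = set(universe[:400])
        ps = []
        for seed in range(60):
            q = set(
                np.random.default_rng(seed).choice(universe, 300, replace=False)
            )
            ps.append(
                nw.overlap_enrichment(q, annotated, universe, n_perm=300,
                                      seed=seed).p
            )
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_pvalue_floor_respected(self, universe):
        res = nw.overlap_enrichment(
            set(universe[:50]), set(universe[:100]), universe, n_perm=100, seed=2
        )
        assert res.p >= 1 / 101

    def test_seed_reproducibility(self, universe):
        args = (set(universe[:30]), set(universe[:200]), universe)
        a = nw.overlap_enrichment(*args, n_perm=500, seed=7)
        b = nw.overlap_enrichment(*args, n_perm=500, seed=7)
        assert (a.p, a.null_mean) == (b.p, b.null_mean)

    def test_empty_inputs_rejected(self, universe):
        with pytest.raises(ValueError):
            nw.overlap_enrichment(set(), set(universe[:10]), universe)


class TestDegreeTest:
    def test_hub_cores_detected(self, hub_network):
        res = nw.degree_test(hub_network, set(hub_network.core_genes), 0.25)
        assert res.p < 0.01
        assert res.core_degrees.mean() > res.other_degrees.mean()

    def test_random_labels_give_uniform_p(self, hub_network):
        ps = []
        for seed in range(40):
            fake = set(
                np.random.default_rng(seed).choice(hub_network.genes, 20,
                                                   replace=False)
            )
            ps.append(nw.degree_test(hub_network, fake, 0.25).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_cutoff_above_all_correlations_degenerate(self, hub_network):
        res = nw.degree_test(hub_network, set(hub_network.core_genes), 0.999)
        assert res.degenerate and res.p == 1.0

    def test_degree_monotone_in_cutoff(self, hub_network):
        d1 = hub_network.degrees(0.2)
        d2 = hub_network.degrees(0.4)
        assert (d2 <= d1).all()

    def test_requires_core_genes(self, hub_network):
        with pytest.raises(ValueError):
            nw.degree_test(hub_network, {"not-a-gene"}, 0.3)


class TestCoexpressionTest:
    def test_correlated_cores_detected(self, hub_network):
        res = nw.core_coexpression_test(
            hub_network, set(hub_network.core_genes), n_perm=1000, seed=0
        )
        assert res.p < 0.01
        assert res.observed_median > np.mean(res.null_medians)

    def test_random_core_set_unremarkable(self, hub_network):
        fake = set(hub_network.genes[100:120])
        res = nw.core_coexpression_test(hub_network, fake, n_perm=500, seed=1)
        assert res.p > 0.01

    def test_constant_matrix_degenerate(self):
        genes = [f"g{i}" for i in range(10)]
        corr = np.full((10, 10), 0.4)
        np.fill_diagonal(corr, 1.0)
        net = bg.simulate.GeneNetwork(
            genes=genes,
            corr=corr,
            flags=pd.DataFrame({"core": [True] * 3 + [False] * 7,
                                "gwas": False},
                               index=pd.Index(genes, name="gene")),
        )
        res = nw.core_coexpression_test(net, set(genes[:3]), n_perm=200, seed=0)
        assert res.observed_median == pytest.approx(np.mean(res.null_medians))
        assert res.p > 0.9

    def test_needs_two_cores(self, hub_network):
        with pytest.raises(ValueError):
            nw.core_coexpression_test(hub_network, {hub_network.genes[0]})


class TestMatchNearest:
    def test_identical_controls_match_exactly(self):
        vals = np.array([1.0, 2.0, 1.0, 2.0])
        treated = np.array([True, True, False, False])
        ctrl = nw.match_nearest(vals, treated)
        assert sorted(vals[ctrl]) == [1.0, 2.0]

    def test_matched_controls_cluster_near_treated_value(self, rng):
        treated_vals = np.full(20, 0.01)
        control_vals = np.linspace(0.005, 0.5, 400)
        vals = np.concatenate([treated_vals, control_vals])
        treated = np.concatenate([np.ones(20, bool), np.zeros(400, bool)])
        ctrl = nw.match_nearest(vals, treated)
        assert np.all(vals[ctrl] < 0.05)

    def test_ratio_two_without_reuse(self):
        vals = np.concatenate([np.zeros(5), np.arange(20.0)])
        treated = np.concatenate([np.ones(5, bool), np.zeros(20, bool)])
        ctrl = nw.match_nearest(vals, treated, ratio=2)
        assert len(ctrl) == 10
        assert len(set(ctrl)) == 10

    def test_insufficient_controls_rejected(self):
        with pytest.raises(ValueError):
            nw.match_nearest(np.arange(4.0), np.array([True, True, True, False]))


class TestMatchedEffectComparison:
    def _variants(self, rng, n=400, boost=1.0, maf_shift=0.0):
        maf = rng.uniform(0.01, 0.5, n)
        core = rng.random(n) < 0.25
        maf[core] = np.clip(maf[core] + maf_shift, 0.01, 0.5)
        beta = np.abs(rng.normal(0.05, 0.02, n)) * np.where(core, boost, 1.0)
        return pd.DataFrame(
            {"abs_beta": beta, "maf": maf,
             "annotation_class": "coding", "core": core}
        )

    def test_null_fold_change_near_one(self):
        fcs = [
            nw.matched_effect_comparison(
                self._variants(np.random.default_rng(s)), seed=s
            ).per_class["fold_change"].iloc[0]
            for s in range(30)
        ]
        assert abs(np.mean(fcs) - 1.0) < 0.1

    def test_doubled_core_betas_detected(self):
        fcs = []
        for s in range(30):
            res = nw.matched_effect_comparison(
                self._variants(np.random.default_rng(100 + s), boost=2.0), seed=s
            )
            fcs.append(res.per_class["fold_change"].iloc[0])
            assert res.per_class["p"].iloc[0] < 0.01
        assert 1.8 < np.mean(fcs) < 2.2

    def test_small_class_skipped(self, rng):
        df = self._variants(rng, n=200)
        small = df.head(30).assign(annotation_class="splice", core=[True] * 9 + [False] * 21)
        res = nw.matched_effect_comparison(pd.concat([df, small]), seed=0)
        assert "splice" in res.skipped
        assert set(res.per_class["annotation_class"]) == {"coding"}

    def test_no_usable_class_rejected(self, rng):
        df = self._variants(rng, n=20).assign(core=[True] * 5 + [False] * 15)
        with pytest.raises(ValueError):
            nw.matched_effect_comparison(df.assign(core=False), seed=0)


class TestTransEqtlEnrichment:
    def test_enriched_generator_detected(self, hub_network):
        eq = bg.simulate_trans_eqtls(hub_network, 2.0, 5000, seed=3)
        res = nw.trans_eqtl_enrichment(eq, set(hub_network.core_genes), seed=3)
        assert res.p < 0.01
        assert 1.5 < res.fold < 2.6

    def test_null_generator_unremarkable(self, hub_network):
        eq = bg.simulate_trans_eqtls(hub_network, 1.0, 5000, seed=4)
        res = nw.trans_eqtl_enrichment(eq, set(hub_network.core_genes), seed=4)
        assert res.p > 0.01
        assert 0.6 < res.fold < 1.5

    def test_degenerate_single_target_refused(self, hub_network):
        eq = bg.simulate_trans_eqtls(hub_network, 1.0, 100, seed=5)
        eq.records["gene"] = hub_network.genes[0]
        with pytest.raises(ValueError, match="degenerate"):
            nw.trans_eqtl_enrichment(eq, set(hub_network.core_genes))


class TestNeighborEnrichment:
    def test_query_equals_universe_unit_fold(self, hub_network):
        res = nw.neighbor_enrichment(
            hub_network, set(hub_network.core_genes), set(hub_network.genes),
            degree=1, cutoff=0.25, n_perm=300, seed=0,
        )
        assert res.fold_enrichment == pytest.approx(1.0, abs=0.02)

    def test_query_inside_first_degree_hits_floor(self, hub_network):
        nbrs = nw.neighbor_set(hub_network, set(hub_network.core_genes), 1, 0.25)
        query = set(list(nbrs)[:30])
        res = nw.neighbor_enrichment(
            hub_network, set(hub_network.core_genes), query,
            degree=1, cutoff=0.25, n_perm=1000, seed=1,
        )
        assert res.p == pytest.approx(1 / 1001)

    def test_second_degree_contains_first(self, hub_network):
        core = set(hub_network.core_genes)
        n1 = nw.neighbor_set(hub_network, core, 1, 0.25)
        n2 = nw.neighbor_set(hub_network, core, 2, 0.25)
        assert n1 <= n2

    def test_degree_domain(self, hub_network):
        with pytest.raises(ValueError):
            nw.neighbor_set(hub_network, set(hub_network.core_genes), 3, 0.3)
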