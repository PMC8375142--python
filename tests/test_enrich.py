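import numpy as np
import pytest

from rnavista import enrich
from rnavista.io import GeneSetDatabase, RegulatorEdge, RegulatorNetwork
from rnavista.stats import HypergeomQuery, hypergeometric_tail

from _oracles import fisher_two_sided_oracle, hypergeom_tail_oracle


def _universe(n):
    return {f"G{i:04d}" for i in range(n)}


class TestORA:
    def test_exact_member_query_ranks_its_set_first(self):
        uni = sorted(_universe(100))
        target = set(uni[:5])
        db = GeneSetDatabase("t", {"TARGET": target,
                                   "OTHER": set(uni[50:80])})
        res = enrich.run_ora(target, db, uni)
        assert res[0].set_name == "TARGET"
        assert res[0].k == 5 and res[0].overlap_genes == frozenset(target)

    def test_set_outside_universe_not_tested(self):
        db = GeneSetDatabase("t", {"GHOST": {"NOPE1", "NOPE2", "NOPE3"}})
        res = enrich.run_ora({"G0001"}, db, _universe(50))
        assert res == []

    def test_planted_counts_match_tail_oracle(self):
        uni = sorted(_universe(1000))
        members = set(uni[:30]) | set(uni[500:520])        # K = 50
        query = set(uni[:30]) | set(uni[100:170])          # n = 100, k = 30
        db = GeneSetDatabase("t", {"PLANTED": members})
        res = enrich.run_ora(query, db, uni)
        assert (res[0].k, res[0].K, res[0].n, res[0].N) == (30, 50, 100, 1000)
        assert res[0].p == pytest.approx(
            hypergeom_tail_oracle(30, 50, 100, 1000), rel=1e-9)
        assert res[0].enrichment_ratio == pytest.approx((30 / 100) / (50 / 1000))

    def test_empty_query_returns_empty(self):
        db = GeneSetDatabase("t", {"S": set(list(_universe(20))[:5])})
        assert enrich.run_ora(set(), db, _universe(20)) == []

    def test_size_window_filters_sets(self):
        uni = sorted(_universe(100))
        db = GeneSetDatabase("t", {"TINY": set(uni[:2]), "OK": set(uni[:10])})
        res = enrich.run_ora(set(uni[:10]), db, uni, min_set=3)
        assert [r.set_name for r in res] == ["OK"]


class TestDirectionalORA:
    def test_all_is_union_of_up_and_down(self, strong_master, strong_bundle):
        c = strong_master.comparisons[0]
        up = set(strong_master.significant_genes(c, "up"))
        down = set(strong_master.significant_genes(c, "down"))
        allg = set(strong_master.significant_genes(c, "all"))
        assert allg == up | down and not up & down

    def test_planted_up_set_enriched_in_up_not_down(self, strong_master,
                                                    strong_bundle):
        c = strong_master.comparisons[0]
        uni = enrich.build_universe(strong_master)
        res = enrich.run_ora_directional(strong_master, c,
                                         strong_bundle.gene_sets, uni)
        planted = [n for n, flag in strong_bundle.truth["gene_sets"].items()
                   if flag]
        up_p = {r.set_name: r.adj_p for r in res["up"]}
        down_p = {r.set_name: r.adj_p for r in res["down"]}
        for name in planted:
            assert up_p[name] < 0.05
            assert down_p.get(name, 1.0) > 0.05

    def test_no_down_genes_is_not_an_error(self, tmp_path):
        # a comparison with zero downregulated genes yields an empty result
        from rnavista.simulate import FixtureConfig, PlantedProfile, \
            generate_experiment
        from rnavista.io import build_master_table
        cfg = FixtureConfig(seed=3, n_genes=300, n_groups=2, reps_per_group=10,
                            profiles=[PlantedProfile(("up",), 40)],
                            n_enriched_sets=1, n_null_sets=5, set_size=20)
        b = generate_experiment(cfg)
        m = build_master_table(b.sheet, b.em, b.comparisons, b.background)
        assert m.significant_genes(m.comparisons[0], "down") == []
        res = enrich.run_ora_directional(m, m.comparisons[0], b.gene_sets,
                                         enrich.build_universe(m))
        assert res["down"] == []


class TestURA:
    @pytest.mark.parametrize("cons,incons,expected_z", [
        (4, 0, 2.0),
        (3, 1, 1.0),
    ])
    def test_activation_z_closed_form(self, cons, incons, expected_z):
        z = (cons - incons) / np.sqrt(cons + incons)
        assert z == pytest.approx(expected_z)

    def test_z_above_two_is_activated(self):
        r = enrich.RegulatorResult(
            regulator="R", overlap_genes=frozenset(), n_consistent=7,
            n_inconsistent=0, n_unknown=0, activation_z=2.5, k=7, K=10,
            n=50, N=500, p=1e-5)
        assert r.state == "activated"
        r.activation_z = -2.5
        assert r.state == "inhibited"
        r.activation_z = 1.9
        assert r.state == "enriched-only"

    def test_counts_and_unknown_mode_policy(self, strong_master):
        # regulon: 3 up-activation (consistent), 1 down-activation
        # (inconsistent), 1 unknown-mode significant target
        c = strong_master.comparisons[0]
        up = strong_master.significant_genes(c, "up")[:3]
        down = strong_master.significant_genes(c, "down")[:1]
        extra = strong_master.significant_genes(c, "up")[3:4]
        sym = dict(zip(strong_master.gene_ids,
                       strong_master.data["symbol"]))
        edges = ([RegulatorEdge("RX", sym[g].upper(), "Activation")
                  for g in up + down]
                 + [RegulatorEdge("RX", sym[g].upper(), "Unknown")
                    for g in extra])
        res = enrich.run_ura(strong_master, c, RegulatorNetwork(edges),
                             enrich.build_universe(strong_master),
                             min_regulon=3)
        (r,) = res
        assert (r.n_consistent, r.n_inconsistent, r.n_unknown) == (3, 1, 1)
        assert r.k == 5                      # unknown still counts in overlap
        assert r.activation_z == pytest.approx(2 / np.sqrt(4))

    def test_planted_regulators_recovered_with_signs(self, strong_master,
                                                     strong_bundle):
        c = strong_master.comparisons[0]
        res = enrich.run_ura(strong_master, c, strong_bundle.network,
                             enrich.build_universe(strong_master))
        states = {r.regulator: r for r in res}
        for name, truth in strong_bundle.truth["regulators"].items():
            if truth == "activated":
                assert states[name].activation_z >= 2
            elif truth == "inhibited":
                assert states[name].activation_z <= -2


class TestSpatial:
    def test_uniform_composition_gives_p_one(self, strong_master):
        # round-robin chromosome assignment spreads calls evenly: direction
        # bias should never be significant after correction
        c = strong_master.comparisons[0]
        res = enrich.run_spatial(strong_master, c)
        assert (res.tables["direction-bias"]["adj_p"] > 0.05).all()

    def test_biased_chromosome_matches_fisher_oracle(self):
        from rnavista.simulate import FixtureConfig, PlantedProfile, \
            generate_experiment
        from rnavista.io import build_master_table
        cfg = FixtureConfig(seed=9, n_genes=400, n_groups=2, reps_per_group=10,
                            profiles=[PlantedProfile(("up",), 40),
                                      PlantedProfile(("down",), 40)],
                            biased_chromosome="chr1",
                            n_enriched_sets=0, n_null_sets=2)
        b = generate_experiment(cfg)
        m = build_master_table(b.sheet, b.em, b.comparisons, b.background)
        res = enrich.run_spatial(m, m.comparisons[0])
        tab = res.tables["direction-bias"]
        row = tab.loc["chr1"]
        assert row["p"] == pytest.approx(
            fisher_two_sided_oracle(int(row["a"]), int(row["b"]),
                                    int(row["c"]), int(row["d"])), rel=1e-9)
        assert row["adj_p"] < 0.05

    def test_gene_without_chromosome_excluded(self, tmp_path):
        import pandas as pd
        from rnavista.io import (BackgroundAnnotation, ComparisonSpec,
                                 DifferentialTable, ExpressionMatrix,
                                 SampleSheet, build_master_table)
        sheet = SampleSheet([("a1", "A"), ("b1", "B")], ["A", "B"])
        genes = ["g1", "g2", "g3"]
        em = ExpressionMatrix(pd.DataFrame(
            [[5, 9], [2, 2], [3, 8]], index=pd.Index(genes, name="gene_id"),
            columns=["a1", "b1"]))
        de = DifferentialTable(pd.DataFrame(
            {"log2fc": [2.0, 0.0, 2.0], "p": [0.001, 0.9, 0.001],
             "adj_p": [0.01, 0.9, 0.01]}, index=pd.Index(genes, name="gene_id")))
        bg = BackgroundAnnotation(pd.DataFrame(
            {"symbol": ["S1", "S2", "S3"], "chromosome": ["chr1", "chr1", ""]},
            index=pd.Index(genes, name="gene_id")))
        comp = ComparisonSpec("B_vs_A", "B", "A", de)
        m = build_master_table(sheet, em, [comp], bg)
        res = enrich.run_spatial(m, "B_vs_A", expressed_threshold=0.0)
        for fam in res.tables.values():
            assert fam[["a", "b", "c", "d"]].to_numpy().sum(axis=None) <= 2 * len(fam)


class TestOverlap:
    def test_identical_lists(self):
        uni = sorted(_universe(100))
        res = enrich.run_overlap(uni[:10], uni[:10], uni)
        assert res.observed == 10
        assert res.enrichment == pytest.approx(100 / 10)

    def test_disjoint_lists_give_p_one(self):
        uni = sorted(_universe(100))
        res = enrich.run_overlap(uni[:10], uni[20:30], uni)
        assert res.observed == 0 and res.p == 1.0

    def test_counts_and_enrichment_closed_form(self):
        uni = sorted(_universe(200))
        A = uni[:20]
        B = uni[10:40]                       # overlap 10, |B| = 30
        res = enrich.run_overlap(A, B, uni)
        assert res.expected == pytest.approx(20 * 30 / 200)
        assert res.enrichment == pytest.approx(10 / 3.0)
        assert res.p == pytest.approx(hypergeom_tail_oracle(10, 20, 30, 200),
                                      rel=1e-9)


class TestSharedGeneNetwork:
    def _res(self, name, genes, adj_p=0.001):
        return enrich.EnrichmentResult(
            set_name=name, overlap_genes=frozenset(genes), k=len(genes),
            K=len(genes), n=10, N=100, enrichment_ratio=2.0, p=adj_p,
            adj_p=adj_p)

    def test_identical_overlaps_share_edge(self):
        G = enrich.build_shared_gene_network(
            [self._res("A", {"X", "Y"}), self._res("B", {"X", "Y"})])
        assert G.has_edge("A", "B")

    def test_disjoint_overlaps_no_edge(self):
        G = enrich.build_shared_gene_network(
            [self._res("A", {"X"}), self._res("B", {"Y"})])
        assert not G.has_edge("A", "B")

    def test_majority_rule_on_smaller_node(self):
        a = self._res("A", {"1", "2", "3", "4", "5"})
        b = self._res("B", {"1", "2", "3", "9", "10", "11", "12", "13"})
        G = enrich.build_shared_gene_network([a, b])
        assert G.has_edge("A", "B")          # 3/5 = 60% of the smaller node

    def test_non_significant_results_excluded(self):
        G = enrich.build_shared_gene_network(
            [self._res("A", {"X"}, adj_p=0.5)])
        assert len(G) == 0


class TestCalibrationAndRecovery:
    def test_null_sets_raw_p_rate_near_nominal(self):
        # 2000 random sets against a random query: raw p < 0.05 should
        # occur at close to the nominal rate
        rng = np.random.default_rng(17)
        uni = sorted(_universe(2000))
        query = set(rng.choice(uni, size=600, replace=False))
        sets = {f"N{i:04d}": set(rng.choice(uni, size=300, replace=False))
                for i in range(2000)}
        res = enrich.run_ora(query, GeneSetDatabase("null", sets), uni,
                             max_set=5000)
        rate = np.mean([r.p < 0.05 for r in res])
        assert 0.03 <= rate <= 0.07

    def test_planted_sets_recovered_across_seeds(self):
        from rnavista.simulate import FixtureConfig, PlantedProfile, \
            generate_experiment
        from rnavista.io import build_master_table
        hits = 0
        total = 0
        for seed in range(10):
            cfg = FixtureConfig(
                seed=seed, n_genes=1000, n_groups=2, reps_per_group=6,
                profiles=[PlantedProfile(("up",), 100),
                          PlantedProfile(("down",), 60)],
                n_enriched_sets=3, n_null_sets=20, set_size=50)
            b = generate_experiment(cfg)
            m = build_master_table(b.sheet, b.em, b.comparisons, b.background)
            res = enrich.run_ora(
                m.symbols_for(m.significant_genes(m.comparisons[0])),
                b.gene_sets, enrich.build_universe(m))
            adj = {r.set_name: r.adj_p for r in res}
            for name, flag in b.truth["gene_sets"].items():
                if flag:
                    total += 1
                    hits += adj.get(name, 1.0) < 0.05
        assert hits / total >= 0.95
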