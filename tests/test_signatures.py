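import numpy as np
import pandas as pd
import pytest

from rnavista.io import build_master_table
from rnavista.signatures import (bin_profiles, compute_metagene,
                                 discover_signatures, merge_signatures)
from rnavista.simulate import FixtureConfig, PlantedProfile, generate_experiment

from _oracles import median_oracle


@pytest.fixture(scope="module")
def planted():
    cfg = FixtureConfig(
        seed=21, n_genes=500, n_groups=3, reps_per_group=30,
        profiles=[PlantedProfile(("up", "up"), 50),
                  PlantedProfile(("up", "down"), 40),
                  PlantedProfile(("down", "ns"), 30)],
        n_enriched_sets=0, n_null_sets=2)
    b = generate_experiment(cfg)
    m = build_master_table(b.sheet, b.em, b.comparisons, b.background)
    return b, m


class TestBinProfiles:
    def test_single_comparison_yields_at_most_two_bins(self):
        cfg = FixtureConfig(seed=2, n_genes=300, n_groups=2, reps_per_group=8,
                            profiles=[PlantedProfile(("up",), 40),
                                      PlantedProfile(("down",), 40)],
                            n_enriched_sets=0, n_null_sets=2)
        b = generate_experiment(cfg)
        m = build_master_table(b.sheet, b.em, b.comparisons, b.background)
        bins = bin_profiles(m)
        assert 1 <= len(bins) <= 2
        assert all(p != ("ns",) for p in (b.profile for b in bins))

    def test_all_ns_genes_are_excluded(self, planted):
        _, m = planted
        bins = bin_profiles(m)
        binned = set().union(*(b.member_genes for b in bins))
        calls = pd.DataFrame({c: m.calls(c) for c in m.comparisons})
        unbinned_ns = calls[~calls.index.isin(binned)]
        assert not unbinned_ns.isin(["up", "down"]).any().any()

    def test_planted_profiles_recovered_exactly(self, planted):
        b, m = planted
        bins = {bb.profile: bb.member_genes for bb in bin_profiles(m)}
        truth: dict[tuple, set] = {}
        for g, info in b.truth["genes"].items():
            if info["signature"] is not None:
                truth.setdefault(tuple(info["profile"]), set()).add(g)
        assert set(bins) == set(truth)
        for prof, genes in truth.items():
            assert bins[prof] == frozenset(genes)


class TestMetagene:
    def test_single_gene_metagene_is_its_z_row(self, planted):
        _, m = planted
        g = m.gene_ids[0]
        assert np.allclose(compute_metagene([g], m),
                           m.zscores().loc[g].to_numpy())

    def test_identical_rows_reproduce_row(self, planted):
        _, m = planted
        g = m.gene_ids[3]
        assert np.allclose(compute_metagene([g, g, g], m),
                           m.zscores().loc[g].to_numpy())

    def test_matches_sort_based_median_oracle(self, planted):
        _, m = planted
        genes = m.gene_ids[:3]
        z = m.zscores().loc[genes].to_numpy(float)
        assert np.allclose(compute_metagene(genes, m), median_oracle(z))


class TestMergeSignatures:
    def test_threshold_one_performs_no_merges(self, planted):
        _, m = planted
        bins = bin_profiles(m)
        ss = merge_signatures(bins, m, scc_threshold=1.0)
        assert ss.merge_log == []
        assert len(ss.signatures) == len(bins)

    def test_identical_metagenes_merge(self):
        # two bins whose genes have identical z rows (SCC = 1 > 0.9) are
        # merged into a single signature; an anti-correlated third is not
        import pandas as pd
        from rnavista.io import (BackgroundAnnotation, ComparisonSpec,
                                 DifferentialTable, ExpressionMatrix,
                                 SampleSheet, build_master_table)
        from rnavista.signatures import ProfileBin
        samples = [(f"s{i}", "A" if i < 3 else "B") for i in range(6)]
        rising = [1.0, 2.0, 4.0, 8.0, 16.0, 32.0]
        falling = rising[::-1]
        em = ExpressionMatrix(pd.DataFrame(
            [rising, rising, falling],
            index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
            columns=[s for s, _ in samples]))
        de = DifferentialTable(pd.DataFrame(
            {"log2fc": [3.0, 3.0, -3.0], "p": [1e-4] * 3,
             "adj_p": [1e-3] * 3},
            index=pd.Index(["g1", "g2", "g3"], name="gene_id")))
        bg = BackgroundAnnotation(pd.DataFrame(
            {"symbol": ["S1", "S2", "S3"], "chromosome": ["1"] * 3},
            index=pd.Index(["g1", "g2", "g3"], name="gene_id")))
        m = build_master_table(SampleSheet(samples, ["A", "B"]), em,
                               [ComparisonSpec("B_vs_A", "B", "A", de)], bg)
        bins = [ProfileBin(("up",), frozenset(["g1"]),
                           compute_metagene(["g1"], m)),
                ProfileBin(("up2",), frozenset(["g2"]),
                           compute_metagene(["g2"], m)),
                ProfileBin(("down",), frozenset(["g3"]),
                           compute_metagene(["g3"], m))]
        ss = merge_signatures(bins, m, scc_threshold=0.9)
        assert len(ss.signatures) == 2
        assert frozenset(["g1", "g2"]) in {s.member_genes
                                           for s in ss.signatures}
        assert len(ss.merge_log) == 1 and ss.merge_log[0][2] == pytest.approx(1.0)

    def test_single_bin_returned_unchanged(self, planted):
        _, m = planted
        bins = bin_profiles(m)[:1]
        ss = merge_signatures(bins, m, scc_threshold=0.5)
        assert len(ss.signatures) == 1 and ss.merge_log == []

    def test_partition_conservation(self, planted):
        _, m = planted
        bins = bin_profiles(m)
        ss = merge_signatures(bins, m, scc_threshold=0.3)
        all_bin_genes = set().union(*(b.member_genes for b in bins))
        all_sig_genes = set().union(*(s.member_genes for s in ss.signatures))
        assert all_sig_genes == all_bin_genes
        sizes = sum(len(s.member_genes) for s in ss.signatures)
        assert sizes == len(all_bin_genes)           # pairwise disjoint

    def test_signature_count_monotone_in_threshold(self, planted):
        _, m = planted
        bins = bin_profiles(m)
        counts = [len(merge_signatures(bins, m, t).signatures)
                  for t in (1.0, 0.9, 0.6, 0.3, 0.0, -1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_idempotent_on_own_output(self, planted):
        _, m = planted
        ss = discover_signatures(m, scc_threshold=0.6)
        from rnavista.signatures import ProfileBin
        rebins = [ProfileBin(tuple(f"sig{s.id}" for _ in m.comparisons),
                             s.member_genes, s.meta_gene)
                  for s in ss.signatures]
        again = merge_signatures(rebins, m, scc_threshold=0.6)
        assert again.merge_log == []
        assert len(again.signatures) == len(ss.signatures)

    def test_two_samples_refuses_to_merge(self):
        cfg = FixtureConfig(seed=4, n_genes=200, n_groups=2, reps_per_group=2,
                            profiles=[PlantedProfile(("up",), 30),
                                      PlantedProfile(("down",), 30)],
                            log2fc_magnitude=4.0,
                            n_enriched_sets=0, n_null_sets=2)
        b = generate_experiment(cfg)
        m = build_master_table(b.sheet, b.em, b.comparisons, b.background)
        bins = bin_profiles(m)
        if len(bins) > 1:
            ss = merge_signatures(bins, m, scc_threshold=-1.0)
            assert ss.merge_log == []

    def test_ranked_by_descending_size(self, planted):
        _, m = planted
        ss = discover_signatures(m, scc_threshold=0.9)
        sizes = [len(s.member_genes) for s in ss.signatures]
        assert sizes == sorted(sizes, reverse=True)
        assert [s.id for s in ss.signatures] == list(
            range(1, len(ss.signatures) + 1))


class TestRecovery:
    def test_well_separated_signatures_recovered(self):
        # four planted profiles whose meta-gene correlations sit well below
        # the merge threshold; high-replicate design so call error is
        # negligible and the check isolates the agglomeration behaviour
        ok = 0
        runs = 10
        for seed in range(runs):
            cfg = FixtureConfig(
                seed=seed + 100, n_genes=600, n_groups=3, reps_per_group=30,
                profiles=[PlantedProfile(("up", "ns"), 60),
                          PlantedProfile(("ns", "up"), 60),
                          PlantedProfile(("up", "down"), 60),
                          PlantedProfile(("down", "up"), 60)],
                n_enriched_sets=0, n_null_sets=2)
            b = generate_experiment(cfg)
            m = build_master_table(b.sheet, b.em, b.comparisons, b.background)
            ss = discover_signatures(m, scc_threshold=0.9)
            truth: dict[int, set] = {}
            for g, info in b.truth["genes"].items():
                if info["signature"]:
                    truth.setdefault(info["signature"], set()).add(g)
            if len(ss.signatures) != len(truth):
                continue
            agree = []
            for s in ss.signatures:
                jac = max(len(s.member_genes & t) / len(s.member_genes | t)
                          for t in truth.values())
                agree.append(jac)
            if min(agree) >= 0.95:
                ok += 1
        assert ok / runs >= 0.9
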