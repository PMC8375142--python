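import json
import re

import pandas as pd
import pytest

from rnavista.registry import CATEGORY_TOTALS, REGISTRY, category_counts
from rnavista.simulate import FixtureConfig, generate_experiment
from rnavista.workflows import WorkflowSpec, run_pipeline_on_bundle


class TestRegistry:
    def test_category_totals_are_pinned(self):
        assert category_counts() == CATEGORY_TOTALS
        assert len(REGISTRY) == sum(CATEGORY_TOTALS.values()) == 50

    def test_workflow_ownership(self):
        assert all(REGISTRY[t].workflow in ("NE", "DE", "MDE")
                   for t in REGISTRY)


class TestWorkflowSpec:
    def test_de_requires_exactly_one_comparison(self):
        with pytest.raises(Exception, match="exactly one"):
            WorkflowSpec(kind="DE", instance_id="x",
                         comparisons=["a", "b"])

    def test_mde_requires_two_comparisons(self):
        with pytest.raises(Exception, match=">= 2"):
            WorkflowSpec(kind="MDE", instance_id="x", comparisons=["a"])


class TestDefaultRun:
    def test_every_artifact_file_exists(self, demo_run):
        outdir, manifest = demo_run
        for inst in manifest["instances"]:
            base = outdir / inst["id"]
            for art in inst["artifacts"]:
                assert (base / art["data_file"]).exists()
                assert (base / art["script_file"]).exists()
                assert (base / art["image_file"]).exists()
                assert (base / art["svg_file"]).exists()

    def test_emitted_type_counts_match_registry(self, demo_run):
        _, manifest = demo_run
        assert manifest["emitted_type_counts"] == CATEGORY_TOTALS

    def test_density_data_is_one_row_per_gene_sample(self, demo_run,
                                                     demo_bundle):
        outdir, manifest = demo_run
        ne = manifest["instances"][0]
        art = next(a for a in ne["artifacts"]
                   if a["plot_type_id"] == "ne_sample_density")
        df = pd.read_csv(outdir / ne["id"] / art["data_file"], sep="\t")
        n_genes = len(demo_bundle.em.gene_ids)
        n_samples = len(demo_bundle.sheet.samples)
        assert len(df) == n_genes * n_samples

    def test_top_expressed_tables_have_top_n_rows_per_group(self, demo_run):
        outdir, manifest = demo_run
        ne = manifest["instances"][0]
        arts = [a for a in ne["artifacts"]
                if a["plot_type_id"] == "ne_top_expressed_table"]
        assert len(arts) == 3                      # one per group
        for art in arts:
            df = pd.read_csv(outdir / ne["id"] / art["data_file"], sep="\t")
            assert len(df) == 5

    def test_counts_bar_matches_master_calls(self, demo_run, demo_master):
        outdir, manifest = demo_run
        de = next(i for i in manifest["instances"] if i["kind"] == "DE")
        comp = de["comparisons"][0]
        art = next(a for a in de["artifacts"]
                   if a["plot_type_id"] == "de_counts_bar")
        df = pd.read_csv(outdir / de["id"] / art["data_file"], sep="\t")
        counts = dict(zip(df["direction"], df["count"]))
        assert counts["up"] == len(demo_master.significant_genes(comp, "up"))
        assert counts["down"] == len(demo_master.significant_genes(comp, "down"))

    def test_volcano_uses_sig_red_ns_black(self, demo_run):
        outdir, manifest = demo_run
        de = next(i for i in manifest["instances"] if i["kind"] == "DE")
        art = next(a for a in de["artifacts"]
                   if a["plot_type_id"] == "de_volcano")
        script = (outdir / de["id"] / art["script_file"]).read_text()
        assert "('ns', 'black'), ('significant', 'red')" in script

    def test_ora_tophits_has_at_most_five_rows(self, demo_run):
        outdir, manifest = demo_run
        de = next(i for i in manifest["instances"] if i["kind"] == "DE")
        art = next(a for a in de["artifacts"]
                   if a["plot_type_id"] == "ora_all_tophits_bar")
        df = pd.read_csv(outdir / de["id"] / art["data_file"], sep="\t")
        assert 0 < len(df) <= 5
        assert {"label", "neglog10_p", "overlap"} <= set(df.columns)

    def test_fold_vs_fold_categories_partition_genes(self, demo_run,
                                                     demo_master):
        outdir, manifest = demo_run
        mde = next(i for i in manifest["instances"] if i["kind"] == "MDE")
        art = next(a for a in mde["artifacts"]
                   if a["plot_type_id"] == "mde_fold_vs_fold")
        df = pd.read_csv(outdir / mde["id"] / art["data_file"], sep="\t")
        c1, c2 = demo_master.comparisons
        both = demo_master.data[[f"{c1}:log2fc", f"{c2}:log2fc"]].dropna()
        assert len(df) == len(both)
        assert set(df["cat"]) <= {"neither", "both", f"{c1} only", f"{c2} only"}

    def test_union_heatmap_rows_equal_union_of_significant(self, demo_run,
                                                           demo_master):
        outdir, manifest = demo_run
        mde = next(i for i in manifest["instances"] if i["kind"] == "MDE")
        art = next(a for a in mde["artifacts"]
                   if a["plot_type_id"] == "mde_union_heatmap_clustered")
        mat = pd.read_csv(outdir / mde["id"] / art["data_file"], sep="\t",
                          index_col=0)
        union = set()
        for c in demo_master.comparisons:
            union |= set(demo_master.significant_genes(c))
        assert len(mat) == len(union)

    def test_metagene_violin_data_is_per_sample_metagene(self, demo_run,
                                                         demo_master):
        from rnavista.signatures import discover_signatures
        import numpy as np
        outdir, manifest = demo_run
        mde = next(i for i in manifest["instances"] if i["kind"] == "MDE")
        arts = [a for a in mde["artifacts"]
                if a["plot_type_id"] == "mde_signature_metagene_violin"]
        ss = discover_signatures(demo_master,
                                 scc_threshold=manifest["params"]["scc_threshold"])
        art = arts[0]
        df = pd.read_csv(outdir / mde["id"] / art["data_file"], sep="\t")
        sig = ss.signatures[0]
        got = df.set_index("sample")["value"]
        expected = pd.Series(sig.meta_gene, index=demo_master.sample_ids)
        assert np.allclose(got[expected.index], expected)

    def test_combined_script_covers_every_plot(self, demo_run):
        outdir, manifest = demo_run
        for inst in manifest["instances"]:
            combined = (outdir / inst["id"] / "scripts" /
                        "combined_workflow.py").read_text()
            assert combined.count("save image") == len(inst["artifacts"])


class TestReport:
    def test_every_artifact_appears_once_with_resolving_anchor(self, demo_run):
        outdir, manifest = demo_run
        for inst in manifest["instances"]:
            html = (outdir / f"{inst['id']}.html").read_text()
            anchors = set(re.findall(r'<section id="([^"]+)"', html))
            hrefs = set(re.findall(r'href="#([^"]+)"', html))
            names = [a["name"] for a in inst["artifacts"]]
            assert anchors == set(names) and len(names) == len(set(names))
            assert hrefs == anchors                 # sidebar links resolve
        index = (outdir / "index.html").read_text()
        for inst in manifest["instances"]:
            assert f'{inst["id"]}.html' in index

    def test_manifest_is_written_and_complete(self, demo_run):
        outdir, manifest = demo_run
        on_disk = json.loads((outdir / "manifest.json").read_text())
        assert on_disk["emitted_type_counts"] == manifest["emitted_type_counts"]
        assert len(on_disk["instances"]) == len(manifest["instances"])


class TestDegenerateRun:
    def test_zero_significant_genes_still_renders(self, tmp_path):
        cfg = FixtureConfig(seed=30, n_genes=120, n_groups=3,
                            reps_per_group=3, profiles=[],
                            n_enriched_sets=0, n_null_sets=4, set_size=10,
                            n_activated=0, n_inhibited=0,
                            n_null_regulators=4, regulon_size=5)
        bundle = generate_experiment(cfg)
        manifest = run_pipeline_on_bundle(bundle, tmp_path / "run", seed=30,
                                          dpi=72)
        assert manifest["emitted_type_counts"] == CATEGORY_TOTALS
        de = next(i for i in manifest["instances"] if i["kind"] == "DE")
        empties = [a for a in de["artifacts"] if a["empty"]]
        assert empties                               # empty states rendered
        for inst in manifest["instances"]:
            assert (tmp_path / "run" / f"{inst['id']}.html").exists()
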