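"""Workflow orchestration: NE / DE / MDE analysis tracks.

A run is a sequence of workflow instances over one master gene table.
Each instance emits, for every plot type in the registry that it owns:
the intermediate data file (exactly the values drawn), a standalone
snippet-composed plot script, and the rendered image (the image is
produced by executing the emitted script, so script re-runnability holds
by construction). A combined per-instance script regenerates every plot
at once, and a machine-readable manifest records every artifact.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrich, signatures as sigmod, stats
from .io import (ComparisonSpec, GeneSetDatabase, MasterGeneTable,
                 RegulatorNetwork, SampleSheet, ValidationError)
from .registry import REGISTRY, category_counts
from .scriptgen import SnippetBin, compose_body, compose_script, \
    compose_workflow_script, load_snippet_bin

log = logging.getLogger("rnavista")

GROUP_PALETTE = ["#d62728", "#2ca02c", "#1f77b4", "#ff7f0e", "#9467bd",
                 "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf"]


@dataclass
class WorkflowSpec:
    """One workflow instance: kind NE/DE/MDE plus its comparisons."""

    kind: str                       # NE | DE | MDE
    instance_id: str
    comparisons: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("NE", "DE", "MDE"):
            raise ValidationError(f"unknown workflow kind {self.kind!r}")
        if self.kind == "DE" and len(self.comparisons) != 1:
            raise ValidationError("a DE workflow takes exactly one comparison")
        if self.kind == "MDE" and len(self.comparisons) < 2:
            raise ValidationError("an MDE workflow needs >= 2 comparisons")


@dataclass
class PlotArtifact:
    """One emitted plot: data + script + image + report text."""

    plot_type_id: str
    instance_id: str
    name: str                       # unique within the instance
    data_file: str
    aux_files: list[str]
    script_file: str
    image_file: str
    svg_file: str
    title: str
    caption: str
    description: str
    methods_text: str
    empty: bool = False


@dataclass
class RunContext:
    """Run-wide configuration shared by every workflow instance."""

    outdir: Path
    bin: SnippetBin
    databases: list[GeneSetDatabase] = field(default_factory=list)
    network: RegulatorNetwork | None = None
    seed: int = 0
    dpi: int = 300
    top_n: int = 5
    scc_threshold: float = 0.9
    expressed_threshold: float = 1.0
    min_set: int = 3
    max_set: int = 2000
    min_regulon: int = 3
    font_size: int = 10
    execute_scripts: bool = True


class _InstanceRunner:
    """Emits the artifacts of one workflow instance."""

    def __init__(self, ctx: RunContext, spec: WorkflowSpec,
                 master: MasterGeneTable):
        self.ctx = ctx
        self.spec = spec
        self.master = master
        self.dir = ctx.outdir / spec.instance_id
        for sub in ("data", "scripts", "plots"):
            (self.dir / sub).mkdir(parents=True, exist_ok=True)
        (self.dir / "analysis").mkdir(exist_ok=True)
        self.artifacts: list[PlotArtifact] = []
        self.blocks: list[str] = []
        order = master.sheet.group_order
        self.group_colors = [(g, GROUP_PALETTE[i % len(GROUP_PALETTE)])
                             for i, g in enumerate(order)]

    # -- shared tag context -------------------------------------------------
    def base_context(self) -> dict[str, object]:
        return {
            "workflow_id": self.spec.instance_id,
            "plot_id": "",
            "font_size": self.ctx.font_size,
            "font_family": "DejaVu Sans",
            "dpi": self.ctx.dpi,
            "group_colors": repr(self.group_colors),
            "sig_color": "red",
            "ns_color": "black",
            "heat_cmap": "RdBu_r",
            "jitter_seed": self.ctx.seed,
            "fig_w": 6.0,
            "fig_h": 4.5,
        }

    # -- emission -----------------------------------------------------------
    def emit(self, plot_id: str, data, tags: dict[str, object], *,
             name: str | None = None, aux: dict[str, pd.DataFrame] | None = None,
             matrix: bool = False, empty_message: str = "no data") -> PlotArtifact:
        """Write data + script for one plot, execute the script, record it."""
        ptype = REGISTRY[plot_id]
        name = name or plot_id
        data_file = f"{name}.tsv"
        if matrix:
            data.to_csv(self.dir / "data" / data_file, sep="\t",
                        index_label=data.index.name or "row")
        else:
            data.to_csv(self.dir / "data" / data_file, sep="\t", index=False)
        aux_files = []
        for suffix, frame in (aux or {}).items():
            f = f"{name}_{suffix}.tsv"
            frame.to_csv(self.dir / "data" / f, sep="\t", index=False)
            aux_files.append(f)

        is_empty = len(data) == 0
        context = self.base_context()
        context.update({
            "plot_id": plot_id,
            "data_file": data_file,
            "image_stem": name,
            "title": ptype.title,
            "empty_message": empty_message,
        })
        context.update(tags)
        override = None
        if is_empty:
            plot_snips = {"bar_vertical", "bar_horizontal", "bar_grouped",
                          "scatter_categorical", "density", "heatmap", "violin",
                          "boxplots", "table_render", "network", "histogram"}
            override = {n: "empty_state"
                        for n in self.ctx.bin.step_configs[plot_id]
                        if n in plot_snips}
        script = compose_script(plot_id, self.ctx.bin, context, override)
        script_file = self.dir / "scripts" / f"{name}.py"
        script_file.write_text(script)
        self.blocks.append(compose_body(plot_id, self.ctx.bin, context, override))

        if self.ctx.execute_scripts:
            exec(compile(script, str(script_file), "exec"),
                 {"__file__": str(script_file), "__name__": "__main__"})

        art = PlotArtifact(
            plot_type_id=plot_id, instance_id=self.spec.instance_id, name=name,
            data_file=f"data/{data_file}",
            aux_files=[f"data/{f}" for f in aux_files],
            script_file=f"scripts/{name}.py",
            image_file=f"plots/{name}.png", svg_file=f"plots/{name}.svg",
            title=ptype.title, caption=ptype.legend,
            description=ptype.description, methods_text=ptype.methods,
            empty=is_empty)
        self.artifacts.append(art)
        return art

    def write_combined_script(self) -> Path:
        context = self.base_context()
        context["plot_id"] = "combined"
        text = compose_workflow_script(self.blocks, self.ctx.bin, context)
        path = self.dir / "scripts" / "combined_workflow.py"
        path.write_text(text)
        return path

    # -- shared data helpers ------------------------------------------------
    def samples_for(self, groups: list[str]) -> list[str]:
        g = self.master.sheet.groups
        return [s for grp in groups for s in g[grp]]

    def group_of(self) -> dict[str, str]:
        return {s: g for s, g in self.master.sheet.samples}

    def long_expression(self, gene_ids: list[str], samples: list[str],
                        value_frame: pd.DataFrame, label: dict[str, str],
                        ) -> pd.DataFrame:
        """Long-format per-sample values for violin/box plots."""
        gof = self.group_of()
        rows = []
        for gid in gene_ids:
            for s in samples:
                rows.append((label.get(gid, gid), s, gof[s],
                             float(value_frame.at[gid, s])))
        return pd.DataFrame(rows, columns=["panel", "sample", "group", "value"])

    def heatmap_matrix(self, gene_ids: list[str], samples: list[str],
                       cluster: bool, labels: dict[str, str] | None = None,
                       order_by: pd.Series | None = None) -> pd.DataFrame:
        """Row-ordered z-score matrix for heatmap plots."""
        z = self.master.zscores().loc[gene_ids, samples]
        if cluster and len(gene_ids) >= 2:
            dend = stats.upgma_cluster(z.to_numpy(float))
            z = z.iloc[dend.leaf_order]
        elif order_by is not None:
            z = z.loc[order_by.loc[gene_ids].sort_values(ascending=False).index]
        if labels:
            z.index = [labels.get(g, g) for g in z.index]
        z.index.name = "gene"
        return z

    def symbol_label(self) -> dict[str, str]:
        d = self.master.data["symbol"]
        return {g: (s if isinstance(s, str) and s.strip() else g)
                for g, s in d.items()}


# ---------------------------------------------------------------------------
# NE workflow
# ---------------------------------------------------------------------------

def run_ne(ctx: RunContext, spec: WorkflowSpec, master: MasterGeneTable,
           ) -> list[PlotArtifact]:
    """Normalized-expression workflow: QC and experiment overview."""
    r = _InstanceRunner(ctx, spec, master)
    sheet = master.sheet
    samples = sheet.sample_ids
    expr = master.expression()
    gof = r.group_of()

    # expression distributions (one row per gene x sample)
    dens = expr.stack().reset_index()
    dens.columns = ["gene", "sample", "value"]
    dens["value"] = np.log10(dens["value"] + 1.0)
    dens["group"] = dens["sample"].map(gof)
    r.emit("ne_sample_density", dens[["sample", "group", "value"]],
           {"value_col": "value", "sample_col": "sample", "group_col": "group",
            "xlab": "log10(expression + 1)"})

    # PCA
    res = stats.pca(expr.to_numpy(float))
    pct = res.percent_variance
    var_df = pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(pct))],
                           "percent": pct})
    r.emit("ne_pca_variance", var_df,
           {"label_col": "component", "value_col": "percent",
            "color_col": "-", "dlabel_col": "-", "bar_color": "steelblue",
            "bar_width": 0.7, "xtick_rotation": 0,
            "xlab": "component", "ylab": "% of variation explained"})
    palette = repr(r.group_colors)
    for pid, (i, j) in (("ne_pca_scatter_12", (0, 1)), ("ne_pca_scatter_34", (2, 3))):
        if res.n_components > j:
            df = pd.DataFrame({"sample": samples,
                               "group": [gof[s] for s in samples],
                               "x": res.scores[:, i], "y": res.scores[:, j]})
        else:
            df = pd.DataFrame(columns=["sample", "group", "x", "y"])
        r.emit(pid, df,
               {"x_col": "x", "y_col": "y", "cat_col": "group",
                "palette": palette, "dot_size": 36, "vlines": "[]",
                "hlines": "[]", "show_legend": True, "annotation": "''",
                "xlab": f"PC{i+1} ({pct[i]:.1f}%)" if res.n_components > i else f"PC{i+1}",
                "ylab": f"PC{j+1} ({pct[j]:.1f}%)" if res.n_components > j else f"PC{j+1}"},
               empty_message="fewer than %d components available" % (j + 1))

    # sample-to-sample Spearman correlation (all genes)
    ranks = expr.rank(axis=0)
    corr = ranks.corr(method="pearson")
    corr.index.name = "sample"
    r.emit("ne_sample_correlation_heatmap", corr,
           {"vlim": "(-1, 1)", "show_row_labels": True, "row_label": "sample",
            "cbar_label": "Spearman correlation"}, matrix=True)

    # highly expressed genes, per group
    label = r.symbol_label()
    means = master.group_means()
    for g in sheet.group_order:
        top = means.sort_values(g, ascending=False).head(ctx.top_n)
        tab = pd.DataFrame({"gene": [label[i] for i in top.index]})
        for gg in sheet.group_order:
            tab[f"mean {gg}"] = top[gg].round(2).to_numpy()
        r.emit("ne_top_expressed_table", tab, {}, name=f"ne_top_expressed_table_{g}")
        top4 = list(means.sort_values(g, ascending=False).head(4).index)
        longv = r.long_expression(top4, samples, expr, label)
        r.emit("ne_top_expressed_violins", longv,
               {"panel_col": "panel", "group_col": "group", "value_col": "value",
                "ylab": "normalized expression", "fig_w": 8.0},
               name=f"ne_top_expressed_violins_{g}")

    # summary table
    rows = []
    for g in sheet.group_order:
        cols = sheet.groups[g]
        sub = expr[cols]
        rows.append((g, len(cols), float(sub.mean().mean()),
                     float(sub.median().median()),
                     int((sub.mean(axis=1) >= ctx.expressed_threshold).sum())))
    summary = pd.DataFrame(rows, columns=["group", "samples", "mean expression",
                                          "median expression", "genes expressed"])
    r.emit("ne_expression_summary_table", summary, {})

    r.write_combined_script()
    return r.artifacts


# ---------------------------------------------------------------------------
# DE workflow
# ---------------------------------------------------------------------------

def _scatter_tags(xlab: str, ylab: str, *, vlines="[]", hlines="[]",
                  annotation="''", palette=None, legend=True) -> dict:
    return {"x_col": "x", "y_col": "y", "cat_col": "cat",
            "palette": palette or "[('ns', 'black'), ('significant', 'red')]",
            "dot_size": 8, "vlines": vlines, "hlines": hlines,
            "show_legend": legend, "annotation": annotation,
            "xlab": xlab, "ylab": ylab}


def _tophits_frame(results, top_n: int) -> pd.DataFrame:
    rows = [(res.set_name if hasattr(res, "set_name") else res.regulator,
             -np.log10(max(res.p, 1e-300)), res.k) for res in results[:top_n]]
    return pd.DataFrame(rows, columns=["label", "neglog10_p", "overlap"])


def _network_frames(G, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    import networkx as nx
    if len(G) == 0:
        return (pd.DataFrame(columns=["node", "x", "y", "size", "intensity"]),
                pd.DataFrame(columns=["source", "target"]))
    pos = nx.spring_layout(G, seed=seed)
    nodes = pd.DataFrame([
        {"node": n, "x": float(pos[n][0]), "y": float(pos[n][1]),
         "size": G.nodes[n]["size"], "intensity": G.nodes[n]["intensity"]}
        for n in sorted(G.nodes)])
    edges = pd.DataFrame(sorted((min(u, v), max(u, v)) for u, v in G.edges),
                         columns=["source", "target"])
    return nodes, edges


def run_de(ctx: RunContext, spec: WorkflowSpec, master: MasterGeneTable,
           comparison: ComparisonSpec) -> list[PlotArtifact]:
    """Differential-expression workflow for one comparison."""
    r = _InstanceRunner(ctx, spec, master)
    c = comparison.name
    test, ref = comparison.test_group, comparison.reference_group
    groups = [g for g in master.sheet.group_order if g in (test, ref)]
    samples = r.samples_for(groups)
    expr = master.expression()
    label = r.symbol_label()
    d = master.data
    calls = master.calls(c)
    l2fc = d[f"{c}:log2fc"]
    pvals = d[f"{c}:p"]
    up_genes = master.significant_genes(c, "up")
    down_genes = master.significant_genes(c, "down")
    sig_genes = up_genes + down_genes

    # counts bar
    counts = pd.DataFrame({"direction": ["up", "down"],
                           "count": [len(up_genes), len(down_genes)],
                           "color": ["red", "blue"]})
    counts["n"] = counts["count"]
    r.emit("de_counts_bar", counts,
           {"label_col": "direction", "value_col": "count", "color_col": "color",
            "dlabel_col": "n", "bar_color": "grey", "bar_width": 0.6,
            "xtick_rotation": 0, "xlab": "",
            "ylab": "significant genes"})

    tested = d[f"{c}:adj_p"].notna()
    sig_cat = pd.Series("ns", index=d.index)
    sig_cat[calls.isin(["up", "down"])] = "significant"

    # MA plot
    ma = pd.DataFrame({
        "x": np.log10(expr[samples].mean(axis=1) + 1.0),
        "y": l2fc, "cat": sig_cat})[tested]
    r.emit("de_ma", ma.dropna(),
           _scatter_tags("log10 mean expression", "log2 fold change",
                         hlines="[0.0]"))

    # volcano
    vol = pd.DataFrame({
        "x": l2fc, "y": -np.log10(np.maximum(pvals, 1e-300)),
        "cat": sig_cat})[tested].dropna()
    t = comparison.abs_log2fc_threshold
    r.emit("de_volcano", vol,
           _scatter_tags("log2 fold change", "-log10 p",
                         vlines=f"[{t}, {-t}]"))

    # fold-change rank
    fr = pd.DataFrame({"y": l2fc, "cat": sig_cat})[tested].dropna()
    fr = fr.sort_values("y", ascending=False)
    fr["x"] = np.arange(1, len(fr) + 1)
    r.emit("de_fold_rank", fr, _scatter_tags("fold-change rank", "log2 fold change"))

    # mean vs mean
    mm = pd.DataFrame({
        "x": np.log10(d[f"mean:{ref}"] + 1.0),
        "y": np.log10(d[f"mean:{test}"] + 1.0), "cat": sig_cat})[tested].dropna()
    r.emit("de_mean_vs_mean", mm,
           _scatter_tags(f"log10 mean expression ({ref})",
                         f"log10 mean expression ({test})"))

    # p-value histogram
    r.emit("de_pvalue_histogram", pd.DataFrame({"p": pvals[tested]}),
           {"value_col": "p", "bins": 40, "bar_color": "steelblue",
            "xlab": "p value"})

    # significant-gene heatmaps
    heat_tags = {"vlim": "None", "show_row_labels": False, "row_label": "genes",
                 "cbar_label": "row z-score", "fig_h": 5.5}
    r.emit("de_sig_heatmap_clustered",
           r.heatmap_matrix(sig_genes, samples, cluster=True),
           heat_tags, matrix=True, empty_message="no significant genes")
    r.emit("de_sig_heatmap_unclustered",
           r.heatmap_matrix(sig_genes, samples, cluster=False, order_by=l2fc),
           heat_tags, matrix=True, empty_message="no significant genes")
    top50 = sorted(sig_genes, key=lambda g: pvals.get(g, 1.0))[:50]
    r.emit("de_labelled_heatmap",
           r.heatmap_matrix(top50, samples, cluster=True, labels=label),
           {**heat_tags, "show_row_labels": True},
           matrix=True, empty_message="no significant genes")

    # top-gene tables and violins (ranked by p)
    def _top_table(genes: list[str], n: int) -> pd.DataFrame:
        genes = sorted(genes, key=lambda g: pvals.get(g, 1.0))[:n]
        return pd.DataFrame({
            "gene": [label[g] for g in genes],
            "log2fc": [round(float(l2fc[g]), 3) for g in genes],
            "p": [float(pvals[g]) for g in genes],
            "adj p": [float(d[f"{c}:adj_p"][g]) for g in genes],
            f"mean {ref}": [round(float(d[f"mean:{ref}"][g]), 2) for g in genes],
            f"mean {test}": [round(float(d[f"mean:{test}"][g]), 2) for g in genes],
        })

    r.emit("de_top_up_table", _top_table(up_genes, ctx.top_n), {},
           empty_message="no upregulated genes")
    r.emit("de_top_down_table", _top_table(down_genes, ctx.top_n), {},
           empty_message="no downregulated genes")
    violin_tags = {"panel_col": "panel", "group_col": "group",
                   "value_col": "value", "ylab": "normalized expression"}
    for pid, pool, k in (("de_top_up_violins", up_genes, 2),
                         ("de_top_down_violins", down_genes, 2),
                         ("de_all_sig_violins", sig_genes, 4)):
        genes = sorted(pool, key=lambda g: pvals.get(g, 1.0))[:k]
        r.emit(pid, r.long_expression(genes, samples, expr, label),
               {**violin_tags, "fig_w": 4.0 + 2.0 * len(genes)},
               empty_message="no significant genes")

    # spatial analysis
    spatial = enrich.run_spatial(master, c, ctx.expressed_threshold)
    for fam, pid in (("expression-bias", "de_spatial_expression_bias"),
                     ("de-bias", "de_spatial_de_bias"),
                     ("direction-bias", "de_spatial_direction_bias")):
        tab = spatial.tables[fam]
        tab.to_csv(r.dir / "analysis" / f"spatial_{fam}.tsv", sep="\t")
        df = pd.DataFrame({
            "chromosome": tab.index,
            "neglog10_adj_p": -np.log10(np.maximum(tab["adj_p"].to_numpy(float),
                                                   1e-300)),
            "n": tab["a"].to_numpy(int)})
        r.emit(pid, df,
               {"label_col": "chromosome", "value_col": "neglog10_adj_p",
                "color_col": "-", "dlabel_col": "n", "bar_color": "steelblue",
                "bar_width": 0.7, "xtick_rotation": 45, "xlab": "chromosome",
                "ylab": "-log10 adjusted p"},
               empty_message="no chromosome annotation")

    # ORA (all / up / down), for the first configured database
    universe = enrich.build_universe(master)
    db = ctx.databases[0] if ctx.databases else GeneSetDatabase("empty", {})
    ora = enrich.run_ora_directional(master, c, db, universe,
                                     ctx.min_set, ctx.max_set)
    tophit_tags = {"label_col": "label", "value_col": "neglog10_p",
                   "color_col": "-", "dlabel_col": "overlap",
                   "bar_color": "steelblue", "xlab": "-log10 p"}
    box_tags = {"panel_col": "panel", "group_col": "group", "value_col": "value",
                "ylab": "expression (z-score)", "fig_w": 8.0}
    zsc = master.zscores()
    sym_to_gene = {}
    for g, s in label.items():
        sym_to_gene.setdefault(s.upper(), g)
    for direction in ("all", "up", "down"):
        results = ora[direction]
        enrich.ora_to_frame(results).to_csv(
            r.dir / "analysis" / f"ora_{direction}.tsv", sep="\t", index=False)
        r.emit(f"ora_{direction}_tophits_bar",
               _tophits_frame(results, ctx.top_n), tophit_tags,
               empty_message="no testable gene sets")
        top_genes = []
        if results and results[0].overlap_genes:
            top_genes = [sym_to_gene[s] for s in sorted(results[0].overlap_genes)
                         if s in sym_to_gene][:12]
        r.emit(f"ora_{direction}_boxplots",
               r.long_expression(top_genes, samples, zsc, label),
               {**box_tags, "title": (results[0].set_name if results else "")},
               empty_message="no enriched gene set")
        nodes, edges = _network_frames(
            enrich.build_shared_gene_network(results), ctx.seed)
        r.emit(f"ora_{direction}_network", nodes, {"edges_file":
               f"ora_{direction}_network_edges.tsv"},
               aux={"edges": edges},
               empty_message="no significantly enriched gene sets")

    # URA
    ura = enrich.run_ura(master, c, ctx.network or RegulatorNetwork([]),
                         universe, ctx.min_regulon)
    enrich.ura_to_frame(ura).to_csv(r.dir / "analysis" / "ura.tsv",
                                    sep="\t", index=False)
    r.emit("ura_enriched_bar", _tophits_frame(ura, ctx.top_n), tophit_tags,
           empty_message="no testable regulators")
    for pid, sign in (("ura_activated_bar", 1), ("ura_inhibited_bar", -1)):
        cand = [x for x in ura if sign * x.activation_z > 0]
        cand.sort(key=lambda x: (-sign * x.activation_z, x.regulator))
        df = pd.DataFrame({
            "label": [x.regulator for x in cand[:ctx.top_n]],
            "z": [x.activation_z for x in cand[:ctx.top_n]],
            "overlap": [x.k for x in cand[:ctx.top_n]]})
        df["color"] = ["red" if abs(z) > 2 else "grey" for z in df["z"]]
        r.emit(pid, df,
               {"label_col": "label", "value_col": "z", "color_col": "color",
                "dlabel_col": "overlap", "bar_color": "grey",
                "xlab": "activation z-score"},
               empty_message="no regulators in this direction")
    top_targets = []
    if ura and ura[0].overlap_genes:
        top_targets = [sym_to_gene[s] for s in sorted(ura[0].overlap_genes)
                       if s in sym_to_gene][:12]
    r.emit("ura_boxplots", r.long_expression(top_targets, samples, zsc, label),
           {**box_tags, "title": (ura[0].regulator if ura else "")},
           empty_message="no enriched regulator")
    nodes, edges = _network_frames(enrich.build_shared_gene_network(ura), ctx.seed)
    r.emit("ura_network", nodes, {"edges_file": "ura_network_edges.tsv"},
           aux={"edges": edges},
           empty_message="no significantly enriched regulators")

    # summary tables
    summary = pd.DataFrame([
        ("comparison", c), ("test group", test), ("reference group", ref),
        ("adj p threshold", comparison.adj_p_threshold),
        ("abs log2fc threshold", comparison.abs_log2fc_threshold),
        ("genes tested", int(tested.sum())),
        ("upregulated", len(up_genes)), ("downregulated", len(down_genes)),
        ("not significant", int((calls == "ns").sum())),
        ("untested", int((calls == "untested").sum())),
    ], columns=["field", "value"])
    r.emit("de_summary_table", summary, {})
    rows = []
    for direction in ("all", "up", "down"):
        for res in ora[direction][:3]:
            rows.append((direction, res.set_name, res.k, res.K,
                         round(res.enrichment_ratio, 2), res.adj_p))
    r.emit("ora_summary_table",
           pd.DataFrame(rows, columns=["query", "gene set", "overlap",
                                       "set size", "ratio", "adj p"]),
           {}, empty_message="no enrichment results")

    r.write_combined_script()
    return r.artifacts


# ---------------------------------------------------------------------------
# MDE workflow
# ---------------------------------------------------------------------------

def run_mde(ctx: RunContext, spec: WorkflowSpec, master: MasterGeneTable,
            comparisons: list[ComparisonSpec]) -> list[PlotArtifact]:
    """Multiple-differential-expression workflow over >= 2 comparisons."""
    r = _InstanceRunner(ctx, spec, master)
    names = [c.name for c in comparisons]
    groups = [g for g in master.sheet.group_order
              if any(g in (c.test_group, c.reference_group) for c in comparisons)]
    samples = r.samples_for(groups)
    d = master.data
    label = r.symbol_label()
    universe = enrich.build_universe(master)

    # per-comparison counts
    rows = []
    for c in names:
        rows.append((c, "up", len(master.significant_genes(c, "up"))))
        rows.append((c, "down", len(master.significant_genes(c, "down"))))
    r.emit("mde_counts_bar",
           pd.DataFrame(rows, columns=["comparison", "direction", "count"]),
           {"cat_col": "comparison", "series_col": "direction",
            "value_col": "count",
            "series_colors": "[('up', 'red'), ('down', 'blue')]",
            "xtick_rotation": 20, "xlab": "", "ylab": "significant genes"})

    # union heatmaps
    union: list[str] = []
    for c in names:
        for g in master.significant_genes(c, "all"):
            if g not in union:
                union.append(g)
    heat_tags = {"vlim": "None", "show_row_labels": False, "row_label": "genes",
                 "cbar_label": "row z-score", "fig_h": 5.5}
    r.emit("mde_union_heatmap_clustered",
           r.heatmap_matrix(union, samples, cluster=True), heat_tags,
           matrix=True, empty_message="no significant genes")
    r.emit("mde_union_heatmap_unclustered",
           r.heatmap_matrix(union, samples, cluster=False,
                            order_by=d[f"{names[0]}:log2fc"]),
           heat_tags, matrix=True, empty_message="no significant genes")

    # overlap (Venn) statistics per comparison pair
    overlap_rows = []
    for a, b in combinations(names, 2):
        A = master.symbols_for(master.significant_genes(a))
        B = master.symbols_for(master.significant_genes(b))
        res = enrich.run_overlap(A, B, universe)
        overlap_rows.append((f"{a} vs {b}", res.size_a, res.size_b, res.observed,
                             round(res.expected, 2), round(res.enrichment, 2),
                             res.p))
    overlap_df = pd.DataFrame(overlap_rows, columns=[
        "pair", "|A|", "|B|", "observed", "expected", "enrichment", "p"])
    overlap_df.to_csv(r.dir / "analysis" / "overlap.tsv", sep="\t", index=False)
    r.emit("mde_overlap_table", overlap_df, {"fig_w": 9.0})
    ov_long = overlap_df.melt(id_vars="pair", value_vars=["observed", "expected"],
                              var_name="kind", value_name="count")
    r.emit("mde_overlap_plot", ov_long,
           {"cat_col": "pair", "series_col": "kind", "value_col": "count",
            "series_colors": "[('observed', 'steelblue'), ('expected', 'lightgrey')]",
            "xtick_rotation": 20, "xlab": "", "ylab": "overlapping genes"})

    # fold versus fold, per comparison pair
    for a, b in combinations(names, 2):
        fa, fb = d[f"{a}:log2fc"], d[f"{b}:log2fc"]
        mask = fa.notna() & fb.notna()
        ca, cb = master.calls(a), master.calls(b)
        sig_a, sig_b = ca.isin(["up", "down"]), cb.isin(["up", "down"])
        cat = pd.Series("neither", index=d.index)
        cat[sig_a & ~sig_b] = f"{a} only"
        cat[~sig_a & sig_b] = f"{b} only"
        cat[sig_a & sig_b] = "both"
        df = pd.DataFrame({"x": fa, "y": fb, "cat": cat})[mask]
        scc = stats.spearman(df["x"], df["y"]) if len(df) >= 3 else float("nan")
        palette = repr([("neither", "black"), (f"{a} only", "green"),
                        (f"{b} only", "blue"), ("both", "red")])
        r.emit("mde_fold_vs_fold", df,
               _scatter_tags(f"log2 fold change ({a})", f"log2 fold change ({b})",
                             palette=palette,
                             annotation=repr(f"SCC = {scc:.2f}")),
               name=f"mde_fold_vs_fold_{a}__{b}")

    # differential expression signatures
    sigset = sigmod.discover_signatures(master, names, ctx.scc_threshold)
    assign = sigset.assignment()
    assign.to_frame("signature").to_csv(r.dir / "analysis" / "signatures.tsv",
                                        sep="\t")
    meta = pd.DataFrame(
        {f"signature_{s.id}": s.meta_gene for s in sigset.signatures},
        index=pd.Index(master.sample_ids, name="sample")).T
    meta.to_csv(r.dir / "analysis" / "signature_metagenes.tsv", sep="\t")
    pd.DataFrame(sigset.merge_log, columns=["merged_a", "merged_b", "scc"]) \
        .to_csv(r.dir / "analysis" / "signature_merge_log.tsv", sep="\t",
                index=False)

    db = ctx.databases[0] if ctx.databases else GeneSetDatabase("empty", {})
    gof = r.group_of()
    violin_tags = {"panel_col": "panel", "group_col": "group",
                   "value_col": "value", "ylab": "meta-gene expression (z-score)"}
    if not sigset.signatures:
        empty = pd.DataFrame(columns=["panel", "group", "value"])
        r.emit("mde_signature_heatmap", pd.DataFrame(), heat_tags, matrix=True,
               empty_message="no signatures found")
        r.emit("mde_signature_metagene_violin", empty, violin_tags,
               empty_message="no signatures found")
        r.emit("mde_signature_ora_bar", pd.DataFrame(columns=["label"]),
               {"label_col": "label", "value_col": "neglog10_p", "color_col": "-",
                "dlabel_col": "overlap", "bar_color": "steelblue",
                "xlab": "-log10 p"},
               empty_message="no signatures found")
    for sig in sigset.signatures:
        members = sorted(sig.member_genes)
        sid = f"signature_{sig.id}"
        r.emit("mde_signature_heatmap",
               r.heatmap_matrix(members, samples, cluster=len(members) > 1),
               {**heat_tags, "title": f"Signature {sig.id} heatmap"},
               matrix=True, name=f"mde_signature_heatmap_{sig.id}")
        mg = pd.DataFrame({
            "panel": f"signature {sig.id}",
            "sample": master.sample_ids,
            "group": [gof[s] for s in master.sample_ids],
            "value": sig.meta_gene})
        mg = mg[mg["group"].isin(groups)]
        r.emit("mde_signature_metagene_violin", mg,
               {**violin_tags, "title": f"Signature {sig.id} meta-gene"},
               name=f"mde_signature_metagene_violin_{sig.id}")
        ora = enrich.run_ora(master.symbols_for(members), db, universe,
                             ctx.min_set, ctx.max_set)
        enrich.ora_to_frame(ora).to_csv(
            r.dir / "analysis" / f"ora_{sid}.tsv", sep="\t", index=False)
        r.emit("mde_signature_ora_bar", _tophits_frame(ora, ctx.top_n),
               {"label_col": "label", "value_col": "neglog10_p", "color_col": "-",
                "dlabel_col": "overlap", "bar_color": "steelblue",
                "xlab": "-log10 p", "title": f"Signature {sig.id} gene-sets"},
               name=f"mde_signature_ora_bar_{sig.id}",
               empty_message="no testable gene sets")

    r.write_combined_script()
    return r.artifacts


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_workflows(master: MasterGeneTable, comparisons: list[ComparisonSpec],
                  specs: list[WorkflowSpec], ctx: RunContext) -> dict:
    """Run every workflow instance and write the run manifest + reports."""
    from . import report as report_mod

    ctx.outdir.mkdir(parents=True, exist_ok=True)
    master.to_tsv(ctx.outdir / "master_gene_table.tsv")
    by_name = {c.name: c for c in comparisons}
    instances = []
    for spec in specs:
        for cname in spec.comparisons:
            if cname not in by_name:
                raise ValidationError(
                    f"workflow {spec.instance_id!r} references unknown "
                    f"comparison {cname!r}")
        if spec.kind == "NE":
            arts = run_ne(ctx, spec, master)
        elif spec.kind == "DE":
            arts = run_de(ctx, spec, master, by_name[spec.comparisons[0]])
        else:
            arts = run_mde(ctx, spec, master,
                           [by_name[n] for n in spec.comparisons])
        instances.append({"id": spec.instance_id, "kind": spec.kind,
                          "comparisons": spec.comparisons,
                          "artifacts": [asdict(a) for a in arts]})

    type_ids = {a["plot_type_id"] for inst in instances for a in inst["artifacts"]}
    emitted = {}
    for tid in type_ids:
        cat = REGISTRY[tid].category
        emitted[cat] = emitted.get(cat, 0) + 1
    manifest = {
        "instances": instances,
        "emitted_type_counts": emitted,
        "registry_type_counts": category_counts(),
        "seed": ctx.seed,
        "params": {"dpi": ctx.dpi, "top_n": ctx.top_n,
                   "scc_threshold": ctx.scc_threshold},
    }
    with open(ctx.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    report_mod.render_report(manifest, ctx.outdir)
    return manifest


def default_workflow_specs(comparisons: list[ComparisonSpec],
                           ) -> list[WorkflowSpec]:
    """The default run layout: one NE, one DE per comparison, one MDE."""
    specs = [WorkflowSpec(kind="NE", instance_id="01_NE")]
    for i, c in enumerate(comparisons, start=2):
        specs.append(WorkflowSpec(kind="DE", instance_id=f"{i:02d}_DE_{c.name}",
                                  comparisons=[c.name]))
    if len(comparisons) >= 2:
        specs.append(WorkflowSpec(
            kind="MDE", instance_id=f"{len(comparisons) + 2:02d}_MDE",
            comparisons=[c.name for c in comparisons]))
    return specs


def run_pipeline_on_bundle(bundle, outdir: str | Path, *, seed: int = 0,
                           scc_threshold: float = 0.9, dpi: int = 150,
                           specs: list[WorkflowSpec] | None = None,
                           execute_scripts: bool = True) -> dict:
    """Convenience driver: run the full default pipeline on an in-memory
    synthetic bundle (used by tests, demos and the acceptance script)."""
    from .io import build_master_table

    master = build_master_table(bundle.sheet, bundle.em, bundle.comparisons,
                                bundle.background)
    ctx = RunContext(outdir=Path(outdir), bin=load_snippet_bin(),
                     databases=[bundle.gene_sets], network=bundle.network,
                     seed=seed, dpi=dpi, scc_threshold=scc_threshold,
                     execute_scripts=execute_scripts)
    specs = specs or default_workflow_specs(bundle.comparisons)
    return run_workflows(master, bundle.comparisons, specs, ctx)
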