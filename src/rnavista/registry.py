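"""The versioned plot-type registry.

Every visualisation the pipeline can emit is declared here with a stable
type id, its category (qc / expression / differential expression /
multiple differential expression), the workflow that owns it, and the
report text attached to each emitted artifact. Category totals are
pinned: qc 1, expression 7, de 33, mde 9 — 50 types overall — and a unit
test keeps them pinned; adjust membership only within those sums.
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PlotType:
    id: str
    category: str           # qc | expression | de | mde
    workflow: str           # NE | DE | MDE
    title: str
    description: str
    legend: str
    methods: str


def _p(pid, cat, wf, title, desc, legend, methods) -> PlotType:
    return PlotType(pid, cat, wf, title, desc, legend, methods)


REGISTRY: dict[str, PlotType] = {p.id: p for p in [
    # ----- NE workflow: 1 qc + 7 expression --------------------------------
    _p("ne_sample_density", "qc", "NE", "Per-sample expression distributions",
       "Density of normalized expression per sample, across all genes.",
       "One density line per sample, coloured by group; expression on a log10 scale.",
       "Gaussian kernel density of log10(expression + 1) per sample."),
    _p("ne_pca_variance", "expression", "NE", "PCA proportion of variance",
       "How much expression variation each principal component explains.",
       "Bar height gives the percent of variation explained by each component.",
       "PCA of log10(x+1), per-gene centred expression via SVD; components 1..min(G, S-1)."),
    _p("ne_pca_scatter_12", "expression", "NE", "PCA: PC1 versus PC2",
       "Sample similarity on the two largest axes of expression variation.",
       "One dot per sample, coloured by group; percent variation on each axis label.",
       "Sample scores from the same PCA as the variance plot."),
    _p("ne_pca_scatter_34", "expression", "NE", "PCA: PC3 versus PC4",
       "Sample structure beyond the first two components.",
       "One dot per sample, coloured by group; percent variation on each axis label.",
       "Sample scores from the same PCA as the variance plot."),
    _p("ne_sample_correlation_heatmap", "expression", "NE",
       "Sample-to-sample correlation heatmap",
       "Pairwise similarity of samples over all genes.",
       "Colour is the Spearman correlation coefficient, -1 darkest blue to +1 darkest red.",
       "Spearman correlation of expression between every pair of samples, all genes."),
    _p("ne_top_expressed_table", "expression", "NE", "Most highly expressed genes",
       "The most highly expressed genes for one group, with every group's mean.",
       "Top 5 genes ranked by the group's mean expression; values are group means.",
       "Genes ranked by per-group mean of normalized expression."),
    _p("ne_top_expressed_violins", "expression", "NE",
       "Expression of the most highly expressed genes",
       "Distribution of expression for the group's top genes.",
       "Violin with black per-sample jitter dots; red dot and whisker give mean +/- SD.",
       "Top 4 genes by the group's mean expression; per-sample normalized values."),
    _p("ne_expression_summary_table", "expression", "NE", "Expression summary",
       "Per-group summary of the expression matrix.",
       "Sample counts and expression summaries per group.",
       "Means/medians over all genes; 'expressed' means mean expression >= 1."),
    # ----- DE workflow: 33 -------------------------------------------------
    _p("de_counts_bar", "de", "DE", "Differential gene counts",
       "How many genes are significantly up- or downregulated.",
       "Bar per direction at the comparison's significance thresholds.",
       "Significance: adjusted p below threshold and |log2 fold| above threshold."),
    _p("de_ma", "de", "DE", "MA plot",
       "Fold change against expression level for every tested gene.",
       "Significant genes red, non-significant black; y is log2 fold change.",
       "x: log10 mean expression of the two groups; thresholds as configured."),
    _p("de_volcano", "de", "DE", "Volcano plot",
       "Fold change against statistical significance for every tested gene.",
       "Significant genes red, non-significant black; dashed lines mark thresholds.",
       "x: log2 fold change, y: -log10 p value."),
    _p("de_sig_heatmap_clustered", "de", "DE", "Significant gene heatmap (clustered)",
       "Expression pattern of every significant gene, genes grouped by similarity.",
       "Row-scaled (z-score) expression, darkest blue lowest to darkest red highest; "
       "rows clustered with Spearman correlations, UPGMA agglomeration and mean reordering.",
       "Per-gene z-scores; rows ordered by UPGMA on 1-SCC with mean reordering."),
    _p("de_sig_heatmap_unclustered", "de", "DE", "Significant gene heatmap (unclustered)",
       "Expression pattern of every significant gene, genes ordered by fold change.",
       "Row-scaled (z-score) expression, darkest blue lowest to darkest red highest.",
       "Per-gene z-scores; rows ordered by log2 fold change."),
    _p("de_labelled_heatmap", "de", "DE", "Top significant genes heatmap (labelled)",
       "Expression pattern of the most significant genes, with gene labels.",
       "As the clustered heatmap, restricted to the top genes by p value with symbols shown.",
       "Top 50 significant genes by p value; clustering as the full heatmap."),
    _p("de_top_up_table", "de", "DE", "Most upregulated genes",
       "The most significantly upregulated genes with their statistics.",
       "Top 5 upregulated genes by p value.",
       "Ranked by p value among genes called up."),
    _p("de_top_down_table", "de", "DE", "Most downregulated genes",
       "The most significantly downregulated genes with their statistics.",
       "Top 5 downregulated genes by p value.",
       "Ranked by p value among genes called down."),
    _p("de_top_up_violins", "de", "DE", "Expression of top upregulated genes",
       "Per-group expression of the most significantly upregulated genes.",
       "Violin with black jitter dots; red dot and whisker give mean +/- SD.",
       "Top 2 upregulated genes by p value; normalized expression per sample."),
    _p("de_top_down_violins", "de", "DE", "Expression of top downregulated genes",
       "Per-group expression of the most significantly downregulated genes.",
       "Violin with black jitter dots; red dot and whisker give mean +/- SD.",
       "Top 2 downregulated genes by p value; normalized expression per sample."),
    _p("de_all_sig_violins", "de", "DE", "Expression of top significant genes",
       "Per-group expression of the most significant genes in either direction.",
       "Violin with black jitter dots; red dot and whisker give mean +/- SD.",
       "Top 4 significant genes by p value."),
    _p("de_pvalue_histogram", "de", "DE", "P-value histogram",
       "Distribution of raw differential p values across all genes.",
       "A spike near zero indicates true differential signal.",
       "Raw (unadjusted) p values, 40 bins."),
    _p("de_fold_rank", "de", "DE", "Fold-change rank plot",
       "All genes ranked by fold change.",
       "Significant genes red, non-significant black.",
       "Genes sorted by log2 fold change; x is the rank."),
    _p("de_mean_vs_mean", "de", "DE", "Group mean versus group mean",
       "Mean expression in the test group against the reference group.",
       "Significant genes red, non-significant black; log10 scale.",
       "Per-group means of normalized expression, log10(x+1)."),
    _p("de_spatial_expression_bias", "de", "DE", "Chromosome expression bias",
       "Whether expressed genes concentrate on particular chromosomes.",
       "-log10 adjusted p per chromosome (Fisher exact, BH-corrected).",
       "2x2 test of expressed vs not, on vs off each chromosome."),
    _p("de_spatial_de_bias", "de", "DE", "Chromosome differential bias",
       "Whether differential genes concentrate on particular chromosomes.",
       "-log10 adjusted p per chromosome (Fisher exact, BH-corrected).",
       "2x2 test of differential vs not among expressed genes, on vs off each chromosome."),
    _p("de_spatial_direction_bias", "de", "DE", "Chromosome direction bias",
       "Whether up- and downregulated genes split unevenly across chromosomes.",
       "-log10 adjusted p per chromosome (Fisher exact, BH-corrected).",
       "2x2 test of up vs down among differential genes, on vs off each chromosome."),
    _p("ora_all_tophits_bar", "de", "DE", "Enriched gene-sets (all significant genes)",
       "The most over-represented gene-sets among all significant genes.",
       "Five most enriched sets; x is -log10 p, data labels give significant-gene counts.",
       "Hypergeometric over-representation with BH correction."),
    _p("ora_all_boxplots", "de", "DE", "Top gene-set expression (all)",
       "Per-gene expression at the most enriched gene-set.",
       "One box per group per gene; expression as per-gene z-scores.",
       "Genes overlapping the top enriched set."),
    _p("ora_all_network", "de", "DE", "Enriched gene-set network (all)",
       "Relationships between significantly enriched gene-sets.",
       "Edges join sets sharing > 50% of their significant genes; node colour -log10 p, "
       "size the significant-gene count.",
       "Nodes: sets at adjusted p < 0.05."),
    _p("ora_up_tophits_bar", "de", "DE", "Enriched gene-sets (upregulated genes)",
       "The most over-represented gene-sets among upregulated genes.",
       "Five most enriched sets; x is -log10 p, data labels give significant-gene counts.",
       "Hypergeometric over-representation with BH correction."),
    _p("ora_up_boxplots", "de", "DE", "Top gene-set expression (up)",
       "Per-gene expression at the most enriched gene-set (up query).",
       "One box per group per gene; expression as per-gene z-scores.",
       "Genes overlapping the top enriched set."),
    _p("ora_up_network", "de", "DE", "Enriched gene-set network (up)",
       "Relationships between gene-sets enriched in upregulated genes.",
       "Edges join sets sharing > 50% of their significant genes.",
       "Nodes: sets at adjusted p < 0.05."),
    _p("ora_down_tophits_bar", "de", "DE", "Enriched gene-sets (downregulated genes)",
       "The most over-represented gene-sets among downregulated genes.",
       "Five most enriched sets; x is -log10 p, data labels give significant-gene counts.",
       "Hypergeometric over-representation with BH correction."),
    _p("ora_down_boxplots", "de", "DE", "Top gene-set expression (down)",
       "Per-gene expression at the most enriched gene-set (down query).",
       "One box per group per gene; expression as per-gene z-scores.",
       "Genes overlapping the top enriched set."),
    _p("ora_down_network", "de", "DE", "Enriched gene-set network (down)",
       "Relationships between gene-sets enriched in downregulated genes.",
       "Edges join sets sharing > 50% of their significant genes.",
       "Nodes: sets at adjusted p < 0.05."),
    _p("ura_enriched_bar", "de", "DE", "Enriched upstream regulators",
       "Regulators whose targets are over-represented among significant genes.",
       "Five most enriched regulators; x is -log10 p, labels give target counts.",
       "Hypergeometric overlap of each regulon with the significant genes, BH-corrected."),
    _p("ura_activated_bar", "de", "DE", "Activated upstream regulators",
       "Regulators inferred as activated from target directions.",
       "Five most activated; x is the activation z-score; significant (z > 2) bars red.",
       "z = (consistent - inconsistent)/sqrt(consistent + inconsistent) over signed targets."),
    _p("ura_inhibited_bar", "de", "DE", "Inhibited upstream regulators",
       "Regulators inferred as inhibited from target directions.",
       "Five most inhibited; x is the activation z-score; significant (z < -2) bars red.",
       "z as for activation; inhibition is z < -2."),
    _p("ura_boxplots", "de", "DE", "Top regulator target expression",
       "Per-gene expression at the most enriched regulator's targets.",
       "One box per group per gene; expression as per-gene z-scores.",
       "Significant targets of the top enriched regulator."),
    _p("ura_network", "de", "DE", "Enriched regulator network",
       "Relationships between significantly enriched upstream regulators.",
       "Edges join regulators sharing > 50% of their regulated genes; colour -log10 p, "
       "size the regulated-gene count.",
       "Nodes: regulators at adjusted p < 0.05."),
    _p("de_summary_table", "de", "DE", "Comparison summary",
       "Headline numbers for the comparison.",
       "Thresholds, tested/called gene counts.",
       "Counts from the master gene table."),
    _p("ora_summary_table", "de", "DE", "Over-representation summary",
       "Top enriched gene-sets across the all/up/down queries.",
       "Best sets per query with overlap, ratio and adjusted p.",
       "Rows are the top sets by p from each directional analysis."),
    # ----- MDE workflow: 9 -------------------------------------------------
    _p("mde_counts_bar", "mde", "MDE", "Significant gene counts per comparison",
       "Up/down counts for every comparison in the analysis.",
       "Grouped bars per comparison and direction.",
       "Counts from the master gene table at each comparison's thresholds."),
    _p("mde_union_heatmap_clustered", "mde", "MDE",
       "All significant genes heatmap (clustered)",
       "Expression of every gene significant in any comparison, grouped by similarity.",
       "Row-scaled (z-score) expression, darkest blue lowest to darkest red highest; "
       "rows clustered with Spearman correlations, UPGMA agglomeration and mean reordering.",
       "Union of significant genes over the comparisons; clustering as in the DE heatmap."),
    _p("mde_union_heatmap_unclustered", "mde", "MDE",
       "All significant genes heatmap (unclustered)",
       "Expression of every gene significant in any comparison.",
       "Row-scaled (z-score) expression; rows ordered by the first comparison's fold change.",
       "Union of significant genes over the comparisons."),
    _p("mde_overlap_table", "mde", "MDE", "Significant gene overlap statistics",
       "Venn-style overlap statistics for every pair of comparisons.",
       "Observed and expected overlap, enrichment and hypergeometric p per pair.",
       "Hypergeometric overlap test against the tested universe."),
    _p("mde_overlap_plot", "mde", "MDE", "Significant gene overlaps",
       "Observed versus expected overlap for every pair of comparisons.",
       "Paired bars per comparison pair.",
       "Same statistics as the overlap table."),
    _p("mde_fold_vs_fold", "mde", "MDE", "Fold versus fold",
       "Gene-level agreement between two comparisons' fold changes.",
       "Red: significant in both; per-comparison colours: significant in one; black: neither. "
       "Overall Spearman correlation annotated.",
       "log2 fold changes of genes present in both differential tables."),
    _p("mde_signature_heatmap", "mde", "MDE", "Signature heatmap",
       "Expression pattern of one differential expression signature.",
       "Row-scaled (z-score) expression of the signature's genes, rows clustered.",
       "Signatures from profile binning and meta-gene SCC merging."),
    _p("mde_signature_metagene_violin", "mde", "MDE", "Signature meta-gene violin",
       "Per-group behaviour of one signature's meta-gene.",
       "Mean expression (z-score) across the signature's genes per sample; black jitter "
       "dots, red mean +/- SD.",
       "Meta-gene: per-sample median of member-gene z-scores."),
    _p("mde_signature_ora_bar", "mde", "MDE", "Signature enriched gene-sets",
       "The most over-represented gene-sets in one signature.",
       "Five most enriched sets; x is -log10 p, data labels give member-gene counts.",
       "Hypergeometric over-representation of the signature's genes, BH-corrected."),
]}

CATEGORY_TOTALS = {"qc": 1, "expression": 7, "de": 33, "mde": 9}


def category_counts() -> dict[str, int]:
    out: dict[str, int] = {}
    for p in REGISTRY.values():
        out[p.category] = out.get(p.category, 0) + 1
    return out


def types_for(workflow: str) -> list[str]:
    return [p.id for p in REGISTRY.values() if p.workflow == workflow]
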