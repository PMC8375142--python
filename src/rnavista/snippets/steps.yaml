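# Per-step configs: the ordered snippet list composed into each step's
# standalone plot script. "plot" marks the snippet swapped for
# empty_state when the step has no data to draw.
ne_sample_density:            [header, theme, load_table, density, save]
ne_pca_variance:              [header, theme, load_table, bar_vertical, save]
ne_pca_scatter_12:            [header, theme, load_table, scatter_categorical, save]
ne_pca_scatter_34:            [header, theme, load_table, scatter_categorical, save]
ne_sample_correlation_heatmap: [header, theme, load_matrix, heatmap, save]
ne_top_expressed_table:       [header, theme, load_table, table_render, save]
ne_top_expressed_violins:     [header, theme, load_table, violin, save]
ne_expression_summary_table:  [header, theme, load_table, table_render, save]

de_counts_bar:                [header, theme, load_table, bar_vertical, save]
de_ma:                        [header, theme, load_table, scatter_categorical, save]
de_volcano:                   [header, theme, load_table, scatter_categorical, save]
de_fold_rank:                 [header, theme, load_table, scatter_categorical, save]
de_mean_vs_mean:              [header, theme, load_table, scatter_categorical, save]
de_pvalue_histogram:          [header, theme, load_table, histogram, save]
de_sig_heatmap_clustered:     [header, theme, load_matrix, heatmap, save]
de_sig_heatmap_unclustered:   [header, theme, load_matrix, heatmap, save]
de_labelled_heatmap:          [header, theme, load_matrix, heatmap, save]
de_top_up_table:              [header, theme, load_table, table_render, save]
de_top_down_table:            [header, theme, load_table, table_render, save]
de_top_up_violins:            [header, theme, load_table, violin, save]
de_top_down_violins:          [header, theme, load_table, violin, save]
de_all_sig_violins:           [header, theme, load_table, violin, save]
de_spatial_expression_bias:   [header, theme, load_table, bar_vertical, save]
de_spatial_de_bias:           [header, theme, load_table, bar_vertical, save]
de_spatial_direction_bias:    [header, theme, load_table, bar_vertical, save]
ora_all_tophits_bar:          [header, theme, load_table, bar_horizontal, save]
ora_all_boxplots:             [header, theme, load_table, boxplots, save]
ora_all_network:              [header, theme, load_network, network, save]
ora_up_tophits_bar:           [header, theme, load_table, bar_horizontal, save]
ora_up_boxplots:              [header, theme, load_table, boxplots, save]
ora_up_network:               [header, theme, load_network, network, save]
ora_down_tophits_bar:         [header, theme, load_table, bar_horizontal, save]
ora_down_boxplots:            [header, theme, load_table, boxplots, save]
ora_down_network:             [header, theme, load_network, network, save]
ura_enriched_bar:             [header, theme, load_table, bar_horizontal, save]
ura_activated_bar:            [header, theme, load_table, bar_horizontal, save]
ura_inhibited_bar:            [header, theme, load_table, bar_horizontal, save]
ura_boxplots:                 [header, theme, load_table, boxplots, save]
ura_network:                  [header, theme, load_network, network, save]
de_summary_table:             [header, theme, load_table, table_render, save]
ora_summary_table:            [header, theme, load_table, table_render, save]

mde_counts_bar:               [header, theme, load_table, bar_grouped, save]
mde_union_heatmap_clustered:  [header, theme, load_matrix, heatmap, save]
mde_union_heatmap_unclustered: [header, theme, load_matrix, heatmap, save]
mde_overlap_table:            [header, theme, load_table, table_render, save]
mde_overlap_plot:             [header, theme, load_table, bar_grouped, save]
mde_fold_vs_fold:             [header, theme, load_table, scatter_categorical, save]
mde_signature_heatmap:        [header, theme, load_matrix, heatmap, save]
mde_signature_metagene_violin: [header, theme, load_table, violin, save]
mde_signature_ora_bar:        [header, theme, load_table, bar_horizontal, save]
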