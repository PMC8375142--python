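# Master config: ordered analysis steps per workflow kind.
# Each step name points at an entry in steps.yaml (the per-step configs),
# which lists the code snippets composed into that step's plot script.
NE:
  - ne_sample_density
  - ne_pca_variance
  - ne_pca_scatter_12
  - ne_pca_scatter_34
  - ne_sample_correlation_heatmap
  - ne_top_expressed_table
  - ne_top_expressed_violins
  - ne_expression_summary_table
DE:
  - de_counts_bar
  - de_ma
  - de_volcano
  - de_fold_rank
  - de_mean_vs_mean
  - de_pvalue_histogram
  - de_sig_heatmap_clustered
  - de_sig_heatmap_unclustered
  - de_labelled_heatmap
  - de_top_up_table
  - de_top_down_table
  - de_top_up_violins
  - de_top_down_violins
  - de_all_sig_violins
  - de_spatial_expression_bias
  - de_spatial_de_bias
  - de_spatial_direction_bias
  - ora_all_tophits_bar
  - ora_all_boxplots
  - ora_all_network
  - ora_up_tophits_bar
  - ora_up_boxplots
  - ora_up_network
  - ora_down_tophits_bar
  - ora_down_boxplots
  - ora_down_network
  - ura_enriched_bar
  - ura_activated_bar
  - ura_inhibited_bar
  - ura_boxplots
  - ura_network
  - de_summary_table
  - ora_summary_table
MDE:
  - mde_counts_bar
  - mde_union_heatmap_clustered
  - mde_union_heatmap_unclustered
  - mde_overlap_table
  - mde_overlap_plot
  - mde_fold_vs_fold
  - mde_signature_heatmap
  - mde_signature_metagene_violin
  - mde_signature_ora_bar
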