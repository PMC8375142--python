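
# ---- {{plot_id}}: load intermediate data (nodes + edges) ----
nodes = pd.read_csv(BASE / "data" / "{{data_file}}", sep="\t")
edges = pd.read_csv(BASE / "data" / "{{edges_file}}", sep="\t")
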