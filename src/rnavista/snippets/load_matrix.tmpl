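
# ---- {{plot_id}}: load intermediate data (matrix) ----
mat = pd.read_csv(BASE / "data" / "{{data_file}}", sep="\t", index_col=0)
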