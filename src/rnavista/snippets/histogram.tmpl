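
# ---- {{plot_id}}: histogram ----
fig, ax = plt.subplots(figsize=({{fig_w}}, {{fig_h}}))
ax.hist(df["{{value_col}}"].dropna(), bins={{bins}}, color="{{bar_color}}",
        edgecolor="white", linewidth=0.3)
ax.set_xlabel("{{xlab}}")
ax.set_ylabel("genes")
ax.set_title("{{title}}")
fig.tight_layout()
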