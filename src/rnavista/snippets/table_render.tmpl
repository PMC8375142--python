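
# ---- {{plot_id}}: table render ----
fig, ax = plt.subplots(figsize=({{fig_w}}, {{fig_h}}))
ax.axis("off")
show = df.copy()
for col in show.columns:
    if show[col].dtype.kind == "f":
        show[col] = show[col].map(lambda v: f"{v:.4g}")
tab = ax.table(cellText=show.astype(str).values,
               colLabels=[str(c) for c in show.columns],
               loc="center", cellLoc="center")
tab.auto_set_font_size(False)
tab.set_fontsize(FONT_SIZE * 0.8)
tab.scale(1, 1.4)
ax.set_title("{{title}}")
fig.tight_layout()
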