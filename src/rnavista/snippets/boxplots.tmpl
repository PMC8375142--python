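
# ---- {{plot_id}}: per-gene grouped boxplots ----
genes = list(dict.fromkeys(df["{{panel_col}}"]))
groups = [g for g, _ in GROUP_COLORS if g in set(df["{{group_col}}"])]
fig, ax = plt.subplots(figsize=({{fig_w}}, {{fig_h}}))
w = 0.8 / max(len(groups), 1)
for gi, g in enumerate(groups):
    data, pos = [], []
    for xi, gene in enumerate(genes):
        sel = (df["{{panel_col}}"] == gene) & (df["{{group_col}}"] == g)
        data.append(df.loc[sel, "{{value_col}}"].to_numpy(float))
        pos.append(xi + (gi - (len(groups) - 1) / 2) * w)
    bp = ax.boxplot(data, positions=pos, widths=w * 0.85, patch_artist=True,
                    medianprops={"color": "black"}, flierprops={"markersize": 3})
    for box in bp["boxes"]:
        box.set_facecolor(GROUP_COLOR_MAP[g])
handles = [plt.Rectangle((0, 0), 1, 1, facecolor=GROUP_COLOR_MAP[g])
           for g in groups]
ax.legend(handles, groups, frameon=False, fontsize=FONT_SIZE * 0.8)
ax.set_xticks(range(len(genes)))
ax.set_xticklabels(genes, rotation=90, fontsize=FONT_SIZE * 0.8)
ax.set_ylabel("{{ylab}}")
ax.set_title("{{title}}")
fig.tight_layout()
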