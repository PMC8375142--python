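
# ---- {{plot_id}}: grouped bar chart ----
fig, ax = plt.subplots(figsize=({{fig_w}}, {{fig_h}}))
cats = list(dict.fromkeys(df["{{cat_col}}"]))
series = list(dict.fromkeys(df["{{series_col}}"]))
series_colors = {{series_colors}}
w = 0.8 / max(len(series), 1)
for si, s in enumerate(series):
    sub = df[df["{{series_col}}"] == s].set_index("{{cat_col}}")
    vals = [float(sub["{{value_col}}"].get(c, 0.0)) for c in cats]
    pos = [i + (si - (len(series) - 1) / 2) * w for i in range(len(cats))]
    ax.bar(pos, vals, width=w * 0.9, label=str(s),
           color=dict(series_colors).get(s, "grey"))
    for x, v in zip(pos, vals):
        ax.annotate(str(int(v)), (x, v), ha="center", va="bottom",
                    fontsize=FONT_SIZE * 0.7)
ax.set_xticks(range(len(cats)))
ax.set_xticklabels([str(c) for c in cats], rotation={{xtick_rotation}},
                   ha="right" if {{xtick_rotation}} else "center")
ax.set_xlabel("{{xlab}}")
ax.set_ylabel("{{ylab}}")
ax.set_title("{{title}}")
ax.legend(frameon=False, fontsize=FONT_SIZE * 0.8)
fig.tight_layout()
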