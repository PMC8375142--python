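
# ---- {{plot_id}}: vertical bar chart ----
fig, ax = plt.subplots(figsize=({{fig_w}}, {{fig_h}}))
labels = df["{{label_col}}"].astype(str).tolist()
values = df["{{value_col}}"].to_numpy(float)
colors = (df["{{color_col}}"].tolist()
          if "{{color_col}}" in df.columns else "{{bar_color}}")
xpos = np.arange(len(labels))
ax.bar(xpos, values, color=colors, width={{bar_width}})
if "{{dlabel_col}}" in df.columns:
    for x, (v, d) in enumerate(zip(values, df["{{dlabel_col}}"])):
        ax.annotate(str(d), (x, v), ha="center", va="bottom",
                    fontsize=FONT_SIZE * 0.8)
ax.set_xticks(xpos)
ax.set_xticklabels(labels, rotation={{xtick_rotation}},
                   ha="right" if {{xtick_rotation}} else "center")
ax.set_xlabel("{{xlab}}")
ax.set_ylabel("{{ylab}}")
ax.set_title("{{title}}")
fig.tight_layout()
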