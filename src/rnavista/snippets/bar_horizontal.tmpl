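
# ---- {{plot_id}}: horizontal top-hits bar chart ----
fig, ax = plt.subplots(figsize=({{fig_w}}, {{fig_h}}))
d = df.iloc[::-1]            # best hit on top
labels = d["{{label_col}}"].astype(str).tolist()
values = d["{{value_col}}"].to_numpy(float)
colors = (d["{{color_col}}"].tolist()
          if "{{color_col}}" in d.columns else "{{bar_color}}")
ypos = np.arange(len(labels))
ax.barh(ypos, values, color=colors)
for y, (v, lab) in enumerate(zip(values, d["{{dlabel_col}}"])):
    ax.annotate(str(lab), (v, y), va="center",
                ha="left" if v >= 0 else "right", fontsize=FONT_SIZE * 0.8)
ax.set_yticks(ypos)
ax.set_yticklabels(labels, fontsize=FONT_SIZE * 0.9)
ax.set_xlabel("{{xlab}}")
ax.set_title("{{title}}")
fig.tight_layout()
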