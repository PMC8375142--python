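
# ---- {{plot_id}}: scatter plot with categorical colouring ----
fig, ax = plt.subplots(figsize=({{fig_w}}, {{fig_h}}))
palette = {{palette}}        # ordered (category, colour) pairs
for cat, color in palette:
    sub = df[df["{{cat_col}}"] == cat]
    ax.scatter(sub["{{x_col}}"], sub["{{y_col}}"], s={{dot_size}},
               c=color, label=str(cat), linewidths=0)
for v in {{vlines}}:
    ax.axvline(v, color="grey", lw=0.8, ls="--")
for h in {{hlines}}:
    ax.axhline(h, color="grey", lw=0.8, ls="--")
if {{show_legend}}:
    ax.legend(frameon=False, fontsize=FONT_SIZE * 0.8)
annot = {{annotation}}
if annot:
    ax.text(0.02, 0.98, annot, transform=ax.transAxes, va="top",
            fontsize=FONT_SIZE * 0.9)
ax.set_xlabel("{{xlab}}")
ax.set_ylabel("{{ylab}}")
ax.set_title("{{title}}")
fig.tight_layout()
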