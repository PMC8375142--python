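
# ---- {{plot_id}}: node-link network (layout precomputed) ----
fig, ax = plt.subplots(figsize=({{fig_w}}, {{fig_h}}))
pos = {r["node"]: (r["x"], r["y"]) for _, r in nodes.iterrows()}
for _, e in edges.iterrows():
    (x0, y0), (x1, y1) = pos[e["source"]], pos[e["target"]]
    ax.plot([x0, x1], [y0, y1], color="lightgrey", lw=1.0, zorder=1)
smax = max(float(nodes["size"].max()), 1.0)
sc = ax.scatter(nodes["x"], nodes["y"],
                s=60 + 240 * nodes["size"] / smax,
                c=nodes["intensity"], cmap="Reds", zorder=2,
                edgecolors="black", linewidths=0.5)
for _, r in nodes.iterrows():
    ax.annotate(str(r["node"]), (r["x"], r["y"]),
                xytext=(0, 6), textcoords="offset points",
                ha="center", fontsize=FONT_SIZE * 0.7)
fig.colorbar(sc, ax=ax, label="-log10 p", fraction=0.04)
ax.set_axis_off()
ax.set_title("{{title}}")
fig.tight_layout()
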