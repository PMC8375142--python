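
# ---- {{plot_id}}: violin + jitter with mean/SD overlay ----
rng = np.random.default_rng(JITTER_SEED)
panels = list(dict.fromkeys(df["{{panel_col}}"]))
fig, axes = plt.subplots(1, max(len(panels), 1),
                         figsize=({{fig_w}}, {{fig_h}}), squeeze=False)
for ax, panel in zip(axes[0], panels):
    sub = df[df["{{panel_col}}"] == panel]
    groups = [g for g, _ in GROUP_COLORS if g in set(sub["{{group_col}}"])]
    data = [sub.loc[sub["{{group_col}}"] == g, "{{value_col}}"]
            .to_numpy(float) for g in groups]
    if all(len(v) > 1 for v in data):
        parts = ax.violinplot(data, positions=range(len(groups)),
                              showextrema=False)
        for body, g in zip(parts["bodies"], groups):
            body.set_facecolor(GROUP_COLOR_MAP[g])
            body.set_alpha(0.5)
    for i, v in enumerate(data):
        ax.scatter(rng.normal(i, 0.05, size=len(v)), v, s=12, c="black",
                   zorder=3)
        mean = v.mean() if len(v) else 0.0
        sd = v.std(ddof=1) if len(v) > 1 else 0.0
        ax.errorbar(i, mean, yerr=sd, fmt="o", color="red", capsize=3,
                    zorder=4)
    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels(groups, rotation=45, ha="right")
    ax.set_title(str(panel), fontsize=FONT_SIZE)
axes[0][0].set_ylabel("{{ylab}}")
fig.suptitle("{{title}}", fontsize=FONT_SIZE * 1.1)
fig.tight_layout()
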