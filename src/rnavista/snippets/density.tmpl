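
# ---- {{plot_id}}: per-sample density (Gaussian kernel) ----
fig, ax = plt.subplots(figsize=({{fig_w}}, {{fig_h}}))
vals = df["{{value_col}}"].to_numpy(float)
grid = np.linspace(vals.min(), vals.max(), 256)
seen = set()
for (sample, group), sub in df.groupby(["{{sample_col}}", "{{group_col}}"],
                                       sort=False):
    x = sub["{{value_col}}"].to_numpy(float)
    bw = 1.06 * x.std(ddof=1) * len(x) ** -0.2 + 1e-9
    dens = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bw) ** 2)
    dens = dens.sum(axis=1) / (len(x) * bw * math.sqrt(2 * math.pi))
    ax.plot(grid, dens, color=GROUP_COLOR_MAP.get(group, "grey"), lw=1.2,
            label=group if group not in seen else None)
    seen.add(group)
ax.legend(frameon=False, fontsize=FONT_SIZE * 0.8, title="group")
ax.set_xlabel("{{xlab}}")
ax.set_ylabel("density")
ax.set_title("{{title}}")
fig.tight_layout()
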