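
# ---- {{plot_id}}: heatmap ----
fig, ax = plt.subplots(figsize=({{fig_w}}, {{fig_h}}))
data = mat.to_numpy(float)
vlim = {{vlim}}              # (vmin, vmax) or None for symmetric max |z|
if vlim is None:
    m = float(np.nanmax(np.abs(data))) if data.size else 1.0
    vlim = (-m if m else -1.0, m if m else 1.0)
im = ax.imshow(data, aspect="auto", cmap=HEAT_CMAP,
               vmin=vlim[0], vmax=vlim[1], interpolation="nearest")
ax.set_xticks(range(mat.shape[1]))
ax.set_xticklabels(mat.columns, rotation=90, fontsize=FONT_SIZE * 0.8)
if {{show_row_labels}} and mat.shape[0] <= 60:
    ax.set_yticks(range(mat.shape[0]))
    ax.set_yticklabels(mat.index, fontsize=FONT_SIZE * 0.7)
else:
    ax.set_yticks([])
    ax.set_ylabel("{{row_label}} (n=%d)" % mat.shape[0])
fig.colorbar(im, ax=ax, label="{{cbar_label}}", fraction=0.04)
ax.set_title("{{title}}")
fig.tight_layout()
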