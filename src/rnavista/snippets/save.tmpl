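
# ---- {{plot_id}}: save image (png + svg) ----
out = BASE / "plots" / "{{image_stem}}"
fig.savefig(str(out) + ".png", dpi=FIG_DPI, metadata={"Software": "rnavista"})
fig.savefig(str(out) + ".svg", metadata={"Date": None})
plt.close(fig)
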