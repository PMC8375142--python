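
# ---- {{plot_id}}: nothing to draw for this analysis ----
fig, ax = plt.subplots(figsize=({{fig_w}}, {{fig_h}}))
ax.axis("off")
ax.text(0.5, 0.5, "{{empty_message}}", ha="center", va="center",
        fontsize=FONT_SIZE)
ax.set_title("{{title}}")
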