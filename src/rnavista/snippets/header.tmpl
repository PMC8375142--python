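# Auto-generated plot script: {{plot_id}} ({{workflow_id}})
# Re-runnable standalone: regenerates the image from the saved data file
# only — no recomputation. Edit visual parameters in the THEME block (or
# edit the snippet bin to change every generated script).
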