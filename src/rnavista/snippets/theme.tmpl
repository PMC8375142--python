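import math
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

# ---- THEME: shared visual parameters (edit here to restyle every plot) ----
FONT_SIZE = {{font_size}}
FONT_FAMILY = "{{font_family}}"
FIG_DPI = {{dpi}}
GROUP_COLORS = {{group_colors}}        # ordered (group, colour) pairs
GROUP_COLOR_MAP = dict(GROUP_COLORS)
SIG_COLOR = "{{sig_color}}"
NS_COLOR = "{{ns_color}}"
HEAT_CMAP = "{{heat_cmap}}"
JITTER_SEED = {{jitter_seed}}
plt.rcParams.update({
    "font.size": FONT_SIZE,
    "font.family": FONT_FAMILY,
    "svg.hashsalt": "rnavista",
    "axes.spines.top": False,
    "axes.spines.right": False,
})
BASE = Path(__file__).resolve().parent.parent
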