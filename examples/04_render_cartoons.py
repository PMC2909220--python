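"""Render plate cartoons with review highlights and a comparison view.

Draws a single-plate cartoon (circle size/color = normalized growth; yellow
halo = below 25% of the plate median; red halo = excluded) and a
side-by-side control/experimental comparison where significant strains are
highlighted red, with a machine-readable legend of their statistics.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from colonygrid.visualize import render_comparison, render_plate

out = Path(tempfile.mkdtemp())
rng = np.random.default_rng(2)

values = rng.lognormal(0, 0.25, (8, 12))     # normalized growth values
low = values < 0.25
excl = np.zeros_like(low)
excl[0, :2] = True                           # pretend a pinning failure
svg = render_plate(values, low_growth=low, excluded=excl,
                   path=out / "plate.svg")
print(f"single-plate cartoon: {out / 'plate.svg'} ({len(svg)} bytes)")

control = np.ones((4, 6))
experimental = np.ones((4, 6))
experimental[1, 2] = 0.3                     # one strong hit
strains = np.array([[f"s{r}_{c}" for c in range(6)] for r in range(4)])
stats = pd.DataFrame([{
    "strain": "s1_2", "orf": "ORF12", "control_mean": 1.0,
    "experimental_mean": 0.3, "growth_ratio": 0.3,
    "log_ratio": 1.2, "z_score": -3.4, "p_value": 0.0007,
    "p_adjusted": 0.0007, "excluded_count": 0,
}])
svg, legend = render_comparison(control, experimental, stats, strains,
                                p_threshold=0.05, out_prefix=out / "cmp")
print(f"comparison cartoon:   {out / 'cmp.svg'}")
print("legend:")
print(legend.to_string(index=False))
# The legend lists every highlighted strain with its position, statistics
# and highlight state (excluded > dead-on-both > significant).
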