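"""PAM-pattern summaries: heatmap, sequence logo and PAM wheel.

Builds the three visual summaries from a synthetic per-PAM table in which
NGGN PAMs are strong, NAGN intermediate and everything else weak — the
canonical-PAM signature — and writes the figures plus their TSV matrices.
"""

import os
import tempfile

import numpy as np
import pandas as pd

from besskit import enumerate_pams, heatmap_matrix, logo_matrix, pam_wheel_tree
from besskit.stats import STATS_COLUMNS
from besskit.viz import plot_heatmap, plot_logo, plot_wheel, wheel_frame

rng = np.random.default_rng(3)
rows = []
for pam in enumerate_pams(4):
    if pam[1:3] == "GG":
        eff, ef = 0.8 + 0.1 * rng.random(), 5 + 3 * rng.random()
    elif pam[1:3] == "AG":
        eff, ef = 0.3 + 0.1 * rng.random(), 1.5 + rng.random()
    else:
        eff, ef = 0.002 * rng.random(), 0.2 * rng.random()
    rows.append(dict(zip(STATS_COLUMNS,
                         [pam, 100, 100, int(100 * eff), eff, 1 / 256,
                          eff / 256, ef, eff > 0.01, ef > 1])))
stats = pd.DataFrame(rows)

hm = heatmap_matrix(stats)
print(f"heatmap: max efficiency {hm.norm_constant:.3f} at "
      f"{hm.row_labels[np.unravel_index(hm.values.argmax(), (16, 16))[0]]}"
      f"{hm.col_labels[np.unravel_index(hm.values.argmax(), (16, 16))[1]]} "
      "(cell value 1.0 after max-normalization)")

functional = stats.loc[stats["functional"], "pam"].tolist()
ef_w = dict(zip(stats["pam"], stats["enrichment_factor"]))
logo = logo_matrix(functional, {p: ef_w[p] for p in functional})
print("logo information content (bits/position):",
      np.round(logo.information, 2))
# ~2 bits at positions 2-3 = near-fixed G/G; ~0 bits = no base preference.

root = pam_wheel_tree({p: ef_w[p] for p in functional})
wf = wheel_frame(root)
ring1 = wf[wf["ring"] == 1].set_index("prefix")["span"]
print("wheel ring-1 arc fractions:",
      {b: round(float(s / (2 * np.pi)), 3) for b, s in ring1.items()})

out = os.path.join(tempfile.gettempdir(), "bess_example_figs")
os.makedirs(out, exist_ok=True)
plot_heatmap(hm, os.path.join(out, "heatmap.svg"))
plot_logo(logo, os.path.join(out, "logo.svg"))
plot_wheel(root, os.path.join(out, "wheel.svg"))
print("figures written to", out)
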