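"""TM-anchor tilt analysis across the four conditions.

The anchor helix tilt ψ is prescribed identically (15°) in every
condition, mirroring the finding that neither protonation nor membrane
composition affects the transmembrane helix orientation: the four
recovered distributions should overlap heavily.
"""

import os

import numpy as np
import pandas as pd

from conditions import CONDITIONS, make_condition
from groovedyn import histogram, select_interval, summarize, tm_tilt_series

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
os.makedirs(OUT, exist_ok=True)

rows = []
for name in CONDITIONS:
    traj, truth = make_condition(name)
    psi = select_interval(tm_tilt_series(traj), 1.0, 5.0)
    dist = histogram(psi, bin_width=2.5)
    stats = summarize(dist)
    pd.DataFrame(
        {"bin_lo": dist.bin_edges[:-1], "bin_hi": dist.bin_edges[1:],
         "density": dist.densities}
    ).to_csv(os.path.join(OUT, f"tm_hist_{name}.tsv"), sep="\t", index=False)
    rows.append({"condition": name, "mean_deg": stats.mean,
                 "width_deg": stats.width,
                 "recovery_err_deg": float(np.abs(
                     tm_tilt_series(traj).values - truth.tm_tilt).mean())})

table = pd.DataFrame(rows)
table.to_csv(os.path.join(OUT, "tm_summary.tsv"), sep="\t", index=False)
print("TM tilt summaries (prescribed 15° everywhere) -> results/tm_summary.tsv")
print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
spread = table.mean_deg.max() - table.mean_deg.min()
print(f"\nspread of condition means: {spread:.2f}° — distributions overlap")
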