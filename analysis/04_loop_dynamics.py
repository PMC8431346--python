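"""α1–α2 loop analysis: Rg distributions and marker-residue z-positions.

Two passes per condition over the 2.25–5.0 μs window: (1) trajectories
with prescribed loop-Rg schedules — recovered Rg distributions must show
the prescribed flexibility contrast (broader in the cardiolipin-analog
conditions); (2) trajectories with Gly-21/Gly-70 pinned at prescribed
z-offsets from the upper phosphate plane — recovered z-distributions must
center on those offsets (membrane-bound at 0, bulk solvent well above).
"""

import os

import pandas as pd

from conditions import CONDITIONS, LOOP_RG, RESIDUE_Z, make_condition
from groovedyn import histogram, residue_z_series, rg_series, select_interval, summarize

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
os.makedirs(OUT, exist_ok=True)

WINDOW = (2.25, 5.0)

rows = []
for name in CONDITIONS:
    traj, truth = make_condition(name)
    rg = select_interval(rg_series(traj), *WINDOW)
    stats = summarize(histogram(rg, bin_width=0.5))
    rows.append({"condition": name, "observable": "rg_A",
                 "prescribed_mean": LOOP_RG[name][0],
                 "prescribed_sd": LOOP_RG[name][1],
                 "mean": stats.mean, "width": stats.width})

    pinned, _ = make_condition(name, residue_pins=True)
    for resid in (21, 70):
        z = select_interval(residue_z_series(pinned, resid), *WINDOW)
        zstats = summarize(histogram(z, bin_width=1.0))
        rows.append({"condition": name, "observable": f"z{resid}_A",
                     "prescribed_mean": RESIDUE_Z[name][resid],
                     "prescribed_sd": 0.5, "mean": zstats.mean,
                     "width": zstats.width})

table = pd.DataFrame(rows)
table.to_csv(os.path.join(OUT, "loop_summary.tsv"), sep="\t", index=False)
print("loop Rg and Gly-21/Gly-70 z summaries over 2.25–5.0 μs "
      "-> results/loop_summary.tsv\n")
print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

wide = table[table.observable == "rg_A"].set_index("condition")["width"]
print("\nRg distribution widths (Å):")
print(f"  cardiolipin-analog conditions broader than matched PC analogs: "
      f"{wide['unprot_pccl'] > wide['unprot_pc'] and wide['prot_pccl'] > wide['prot_pc']}")
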