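"""Groove-orientation analysis of the four synthetic conditions.

Recomputes the BH3-groove deviation angle ϕ(t) from the trajectory
coordinates of every condition, discards the declared non-stationary first
microsecond, histograms ϕ over two stationary windows, and summarizes the
occluded/accessible balance.  Compares the recovered series against the
prescribed ground truth.
"""

import os

import numpy as np
import pandas as pd

from conditions import CONDITIONS, make_condition
from groovedyn import (
    classify_accessibility,
    groove_angle_series,
    histogram,
    select_interval,
    summarize,
)

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
os.makedirs(OUT, exist_ok=True)

WINDOWS = {"window1": (1.0, 3.0), "window2": (3.0, 5.0)}

rows = []
for name in CONDITIONS:
    traj, truth = make_condition(name)
    phi = groove_angle_series(traj)
    err = np.abs(phi.values - truth.groove_angle)
    stationary = select_interval(phi, 1.0, 5.0)
    occluded = np.mean(
        [classify_accessibility(v) == "occluded" for v in stationary.values]
    )
    pd.DataFrame(
        {"time_us": phi.times, "phi_deg": phi.values,
         "phi_truth_deg": truth.groove_angle}
    ).to_csv(os.path.join(OUT, f"groove_{name}.tsv"), sep="\t", index=False)
    for wname, (t0, t1) in WINDOWS.items():
        dist = histogram(select_interval(phi, t0, t1), bin_width=2.5)
        stats = summarize(dist)
        pd.DataFrame(
            {"bin_lo": dist.bin_edges[:-1], "bin_hi": dist.bin_edges[1:],
             "density": dist.densities}
        ).to_csv(os.path.join(OUT, f"groove_hist_{name}_{wname}.tsv"),
                 sep="\t", index=False)
        rows.append(
            {"condition": name, "window": wname, "mean_deg": stats.mean,
             "mode_lo": stats.mode_bin[0], "mode_hi": stats.mode_bin[1],
             "width_deg": stats.width, "n_frames": dist.n_frames}
        )
    print(f"{name:12s}: mean recovery error {err.mean():.2f}° "
          f"(atomic noise 0.5 Å); occluded fraction t≥1 μs: {occluded:.2f}")

summary = pd.DataFrame(rows)
summary.to_csv(os.path.join(OUT, "groove_interval_summary.tsv"), sep="\t",
               index=False)
print("\nper-interval groove-angle summaries -> results/groove_interval_summary.tsv")
print(summary.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
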