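"""The four synthetic study conditions shared by the analysis scripts.

The real study crossed two protonation states with two membrane
compositions (100% POPC vs 2:1 POPC:TOCL) and observed qualitatively
different groove-orientation and loop behaviours.  The synthetic analogs
below prescribe those behaviours as ground-truth schedules on the toy
anchored protein, so every downstream analysis runs against known truth:

* ``unprot_pc``    — groove mostly occluded with a sharp ~1 μs excursion to
                     an accessible orientation (40°) and back; stiff loop.
* ``unprot_pccl``  — large mean-reverting fluctuations in the 90–110°
                     band; flexible (broad-Rg) loop.
* ``prot_pc``      — small fluctuations about ~95°; stiff loop, up-shifted
                     Rg (extended).
* ``prot_pccl``    — gradual sustained rotation converging below 90°
                     (accessible); flexible loop, down-shifted Rg.

Each condition is a 500-frame, 5 μs rigid-body trajectory (0.01 μs/frame)
with 0.5 Å atomic noise.  Loop-Rg targets are mean-reverting AR(1) series
whose spread encodes the loop-flexibility contrast; marker-residue
z-offsets place Gly-70 in bulk solvent for the unprotonated conditions and
at the phosphate plane for the protonated ones.
"""

from __future__ import annotations

import numpy as np

from groovedyn import (
    AngleSchedule,
    make_anchored_toy,
    make_membrane_slab,
    make_rigid_body_trajectory,
)

N_FRAMES = 500
DT_US = 0.01
NOISE_SD = 0.5
BASE_SEED = 2021

GROOVE_SCHEDULES = {
    "unprot_pc": AngleSchedule(
        "piecewise", levels=[100.0, 40.0, 100.0], switch_fractions=[0.55, 0.75]
    ),
    "unprot_pccl": AngleSchedule("ou", mean=100.0, sd=6.0, tau_us=0.1),
    "prot_pc": AngleSchedule("ou", mean=95.0, sd=3.0, tau_us=0.1),
    "prot_pccl": AngleSchedule("linear", levels=[100.0, 75.0]),
}

# loop Rg targets: (mean Å, AR(1) stationary sd Å)
LOOP_RG = {
    "unprot_pc": (9.5, 0.3),
    "unprot_pccl": (9.5, 1.0),
    "prot_pc": (11.0, 0.3),
    "prot_pccl": (10.0, 0.8),
}

# marker-residue z-offsets from the upper phosphate plane (Å)
RESIDUE_Z = {
    "unprot_pc": {21: 2.0, 70: 15.0},
    "unprot_pccl": {21: 6.0, 70: 15.0},
    "prot_pc": {21: 10.0, 70: 0.0},
    "prot_pccl": {21: 0.0, 70: 0.0},
}

CONDITIONS = list(GROOVE_SCHEDULES)


def ar1_series(mean: float, sd: float, n: int, rng, tau_frames: float = 10.0):
    """Mean-reverting target series with stationary mean/sd (exact update)."""
    alpha = np.exp(-1.0 / tau_frames)
    x = np.empty(n)
    x[0] = mean + sd * rng.standard_normal()
    scale = sd * np.sqrt(1 - alpha**2)
    for k in range(1, n):
        x[k] = mean + (x[k - 1] - mean) * alpha + scale * rng.standard_normal()
    return np.clip(x, 2.0, None)


def make_condition(name: str, residue_pins: bool = False):
    """(trajectory, truth) for one named condition.

    ``residue_pins=True`` scripts the Gly-21/Gly-70 z-offsets instead of
    the loop-Rg schedule (the two prescriptions are mutually exclusive:
    pinning individual atoms perturbs the realized Rg).
    """
    seed = BASE_SEED + CONDITIONS.index(name)
    rng = np.random.default_rng(seed + 1000)
    toy = make_anchored_toy()
    slab = make_membrane_slab(seed=seed)
    kwargs = {}
    if residue_pins:
        kwargs["residue_z"] = RESIDUE_Z[name]
    else:
        mean, sd = LOOP_RG[name]
        kwargs["loop_rg"] = ar1_series(mean, sd, N_FRAMES, rng)
    return make_rigid_body_trajectory(
        toy,
        slab,
        GROOVE_SCHEDULES[name],
        n_frames=N_FRAMES,
        dt_us=DT_US,
        tm_tilt_deg=15.0,
        noise_sd=NOISE_SD,
        seed=seed,
        **kwargs,
    )
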