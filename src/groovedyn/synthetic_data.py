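"""Synthetic fixtures with known ground truth.

Real microsecond trajectories of a membrane-anchored protein are not
regenerable at desk scale, so every pipeline stage is exercised on
synthetic data instead: ideal Cα helices, a toy two-domain protein (rigid
soluble head + transmembrane anchor helix) using the production residue
numbering, phosphate-bead membrane slabs, and rigid-body trajectories in
which the groove deviation angle ϕ(t), the TM tilt ψ(t) and the loop radius
of gyration follow prescribed schedules *exactly* (rotations are built from
the recomputed reference vectors, so descriptor recovery is limited only by
floating point).

Schedules mimic the qualitative behaviours seen in such simulations: steady
fluctuation about a level (an Ornstein–Uhlenbeck process, discretized with
its exact conditional law so the stationary moments are analytic), sharp
piecewise transitions, and gradual linear rotations.  All randomness is
seeded; identical seeds give identical coordinates.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .groove_geometry import (
    ALPHA8,
    GrooveVectorDef,
    groove_vector,
    helix_principal_axis,
)
from .loop_descriptors import LoopDefinition, radius_of_gyration
from .membrane_geometry import membrane_frame
from .model_builder import _rotation_between
from .structure_io import (
    MolecularModel,
    Trajectory,
    merge_models,
    write_trajectory,
)

__all__ = [
    "AngleSchedule",
    "SyntheticGroundTruth",
    "make_ideal_helix",
    "make_membrane_slab",
    "make_anchored_toy",
    "make_rigid_body_trajectory",
    "write_fixture",
]

#: OU draws are clipped into this open sub-range of (0, 180) degrees
OU_CLIP = (0.5, 179.5)


@dataclass(frozen=True)
class AngleSchedule:
    """Prescribed time course of an angle in degrees.

    kinds:
      ``constant``  — ``levels=[value]``
      ``piecewise`` — ``levels`` plus ``switch_fractions`` (fractions of the
                      frame count at which the level changes; sharp)
      ``linear``    — ramp from ``levels[0]`` to ``levels[1]``
      ``ou``        — mean-reverting fluctuation: ``mean``, ``sd``
                      (stationary), ``tau_us`` (correlation time)
    """

    kind: str
    levels: Sequence[float] = ()
    switch_fractions: Sequence[float] = ()
    mean: float = 100.0
    sd: float = 5.0
    tau_us: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "piecewise", "linear", "ou"):
            raise ConfigError(f"unknown schedule kind {self.kind!r}")
        for level in self.levels:
            if not 0.0 < level < 180.0:
                raise ConfigError(
                    f"schedule level {level}° outside the open range (0, 180)"
                )
        if self.kind == "constant" and len(self.levels) != 1:
            raise ConfigError("constant schedule needs exactly one level")
        if self.kind == "linear" and len(self.levels) != 2:
            raise ConfigError("linear schedule needs exactly two levels")
        if self.kind == "piecewise":
            if len(self.levels) < 1:
                raise ConfigError("piecewise schedule needs at least one level")
            if len(self.switch_fractions) != len(self.levels) - 1:
                raise ConfigError(
                    "need len(switch_fractions) == len(levels) - 1"
                )
            fr = list(self.switch_fractions)
            if fr != sorted(fr) or any(not 0.0 < f < 1.0 for f in fr):
                raise ConfigError(
                    "switch_fractions must be increasing and inside (0, 1)"
                )
        if self.kind == "ou":
            if not 0.0 < self.mean < 180.0:
                raise ConfigError("OU mean must lie in (0, 180)")
            if self.sd <= 0 or self.tau_us <= 0:
                raise ConfigError("OU sd and tau_us must be positive")

    def sample(
        self, n_frames: int, dt_us: float, rng: np.random.Generator | None = None
    ) -> np.ndarray:
        if n_frames < 1:
            raise ConfigError("need at least one frame")
        if self.kind == "constant":
            return np.full(n_frames, float(self.levels[0]))
        if self.kind == "linear":
            return np.linspace(self.levels[0], self.levels[1], n_frames)
        if self.kind == "piecewise":
            out = np.empty(n_frames)
            switches = [0] + [round(f * n_frames) for f in self.switch_fractions]
            switches.append(n_frames)
            for level, lo, hi in zip(self.levels, switches[:-1], switches[1:]):
                out[lo:hi] = level
            return out
        # exact OU: x_{k+1} = mu + (x_k - mu) a + sd sqrt(1 - a^2) xi
        if rng is None:
            raise ConfigError("an OU schedule needs a seeded random generator")
        alpha = float(np.exp(-dt_us / self.tau_us))
        noise = rng.standard_normal(n_frames)
        out = np.empty(n_frames)
        out[0] = self.mean + self.sd * noise[0]
        scale = self.sd * np.sqrt(1.0 - alpha**2)
        for k in range(1, n_frames):
            out[k] = self.mean + (out[k - 1] - self.mean) * alpha + scale * noise[k]
        return np.clip(out, *OU_CLIP)


@dataclass
class SyntheticGroundTruth:
    """Prescribed per-frame values stored alongside a generated trajectory."""

    groove_angle: np.ndarray
    tm_tilt: np.ndarray
    loop_rg: np.ndarray | None = None
    residue_z: Mapping[int, np.ndarray] = field(default_factory=dict)
    seed: int | None = None
    description: str = ""

    def __post_init__(self) -> None:
        self.groove_angle = np.asarray(self.groove_angle, dtype=np.float64)
        self.tm_tilt = np.asarray(self.tm_tilt, dtype=np.float64)
        n = len(self.groove_angle)
        arrays = {"tm_tilt": self.tm_tilt}
        if self.loop_rg is not None:
            self.loop_rg = np.asarray(self.loop_rg, dtype=np.float64)
            arrays["loop_rg"] = self.loop_rg
        self.residue_z = {
            int(k): np.asarray(v, dtype=np.float64) for k, v in self.residue_z.items()
        }
        arrays.update({f"z{k}": v for k, v in self.residue_z.items()})
        for name, arr in arrays.items():
            if len(arr) != n:
                raise ConfigError(f"ground-truth field {name} length != {n}")
            if not np.isfinite(arr).all():
                raise ConfigError(f"ground-truth field {name} has non-finite values")
        if not np.isfinite(self.groove_angle).all():
            raise ConfigError("ground-truth groove angles must be finite")


def make_ideal_helix(
    n_res: int = 23,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    start_residue: int = 1,
    chain_id: str = "A",
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    n_to_c: str = "up",
) -> MolecularModel:
    """Cα trace of an ideal α-helix built along +z (then optionally moved).

    Defaults are canonical α-helix parameters: 1.5 Å rise and 100° twist
    per residue, 2.3 Å helical radius.  ``n_to_c="down"`` builds the chain
    running toward −z instead.

    A finite discrete helix generically has a small inertia-axis tilt
    (the x–z and y–z cross moments do not cancel over a non-integer number
    of turns), so the trace is de-sheared — the per-coordinate regression
    on z is removed — making the principal axis of the Cα inertia tensor
    equal to the build axis *exactly*, by construction.  The correction is
    a fraction of an Å and leaves the trace visually helical.
    """
    if n_res < 3:
        raise ConfigError("an ideal helix needs at least 3 residues")
    if rise <= 0 or radius <= 0:
        raise ConfigError("rise and radius must be positive")
    if n_to_c not in ("up", "down"):
        raise ConfigError("n_to_c must be 'up' or 'down'")
    i = np.arange(n_res)
    theta = np.radians(twist) * i
    z = rise * i
    if n_to_c == "down":
        z = -z
    xyz = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
    xyz -= xyz.mean(axis=0)
    # de-shear: zero the x-z and y-z inertia cross terms so z is an exact
    # eigenvector of the inertia tensor
    zz = xyz[:, 2] @ xyz[:, 2]
    for k in (0, 1):
        xyz[:, k] -= (xyz[:, k] @ xyz[:, 2]) / zz * xyz[:, 2]
    model = MolecularModel(
        atom_names=np.full(n_res, "CA"),
        elements=np.full(n_res, "C"),
        residue_names=np.full(n_res, "ALA"),
        residue_numbers=start_residue + i,
        chain_ids=np.full(n_res, chain_id),
        positions=xyz,
    )
    return model.transformed(rotation, translation)


def make_membrane_slab(
    n_per_leaflet: int = 100,
    half_gap: float = 14.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    box_xy: float = 90.0,
    chain_id: str = "M",
) -> MolecularModel:
    """Phosphate-bead bilayer stand-in: two planes of P atoms at ±half_gap Å
    (plus optional Gaussian z-noise), on an x–y grid of side ``box_xy``."""
    if n_per_leaflet < 1:
        raise ConfigError("need at least one bead per leaflet")
    if half_gap <= 0:
        raise ConfigError("half_gap must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(n_per_leaflet)))
    grid = (np.arange(side) + 0.5) / side * box_xy - box_xy / 2.0
    gx, gy = np.meshgrid(grid, grid)
    xy = np.column_stack([gx.ravel(), gy.ravel()])[:n_per_leaflet]
    n = 2 * n_per_leaflet
    z = np.concatenate(
        [np.full(n_per_leaflet, half_gap), np.full(n_per_leaflet, -half_gap)]
    )
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, size=n)
    return MolecularModel(
        atom_names=np.full(n, "P"),
        elements=np.full(n, "P"),
        residue_names=np.full(n, "POP"),
        residue_numbers=np.arange(1, n + 1),
        chain_ids=np.full(n, chain_id),
        positions=np.column_stack([np.tile(xy, (2, 1)), z]),
    )


def _line_segment(
    residues: np.ndarray, origin: np.ndarray, direction: np.ndarray, spacing: float = 1.5
) -> np.ndarray:
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return origin + spacing * np.arange(len(residues))[:, None] * d


def make_anchored_toy(
    head_z: float = 24.0,
    loop_radius: float = 14.0,
    loop: LoopDefinition | None = None,
    tm_first: int = 209,
    tm_last: int = 231,
) -> MolecularModel:
    """Cα-only toy of the anchored architecture, on production numbering.

    Head (residues 1–207): helix α1 (1–20), the long α1–α2 loop (21–81,
    a semicircular arc of radius ``loop_radius`` so its Rg is tunable),
    helix α5 (143–153, axis ≈ +x), helix α6 (164–181, offset 12 Å in +y),
    and extended filler in between.  Anchor helix α8 (209–231) runs along
    z centered on the bilayer midplane, N-terminal end (209) up toward the
    head, as in the real topology.  Gly-21/Gly-70, Gln-207 and Trp-213
    carry their real residue names so production selections apply
    unchanged.  The default dimensions pair with the default 28 Å
    phosphate-plane separation of :func:`make_membrane_slab`, which the
    34.5 Å Cα anchor helix can span while keeping the anchor residue just
    below the upper plane.
    """
    loop = loop or LoopDefinition()
    segs: list[tuple[np.ndarray, np.ndarray]] = []  # (residue numbers, coords)

    helix1 = make_ideal_helix(
        20,
        start_residue=1,
        rotation=_rotation_between(np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])),
        translation=np.array([-2.0, -14.0, head_z + 8.0]),
    )
    segs.append((helix1.residue_numbers, helix1.positions))

    n_loop = loop.n_residues
    ang = np.linspace(0.0, np.pi, n_loop)
    loop_xyz = np.column_stack(
        [
            loop_radius * np.cos(ang),
            np.full(n_loop, -8.0),
            head_z + 6.0 - loop_radius * np.sin(ang),
        ]
    )
    segs.append((np.arange(loop.first, loop.last + 1), loop_xyz))

    filler1 = np.arange(loop.last + 1, 143)
    segs.append(
        (filler1, _line_segment(filler1, np.array([-12.0, -4.0, head_z + 10.0]), [1, 0, 0]))
    )

    helix5 = make_ideal_helix(
        11,
        start_residue=143,
        rotation=_rotation_between(np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])),
        translation=np.array([0.0, 0.0, head_z]),
    )
    segs.append((helix5.residue_numbers, helix5.positions))

    filler2 = np.arange(154, 164)
    segs.append(
        (filler2, _line_segment(filler2, np.array([9.0, 3.0, head_z - 1.0]), [0, 1, 0]))
    )

    helix6 = make_ideal_helix(
        18,
        start_residue=164,
        rotation=_rotation_between(np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])),
        translation=np.array([0.0, 12.0, head_z - 2.0]),
    )
    segs.append((helix6.residue_numbers, helix6.positions))

    filler3 = np.arange(182, 208)
    segs.append(
        (filler3, _line_segment(filler3, np.array([-14.0, 8.0, head_z + 4.0]), [1, 0, 0]))
    )

    n_tm = tm_last - tm_first + 1
    # anchor helix along z, centered on the midplane, residue 209 at the top
    tm = make_ideal_helix(n_tm, start_residue=tm_first, n_to_c="down")
    segs.append((tm.residue_numbers, tm.positions))

    residues = np.concatenate([s[0] for s in segs])
    xyz = np.vstack([s[1] for s in segs])
    names = np.full(len(residues), "ALA", dtype="U4")
    names[np.isin(residues, (21, 70))] = "GLY"
    names[residues == 207] = "GLN"
    names[residues == 213] = "TRP"
    return MolecularModel(
        atom_names=np.full(len(residues), "CA"),
        elements=np.full(len(residues), "C"),
        residue_names=names,
        residue_numbers=residues,
        chain_ids=np.full(len(residues), "A"),
        positions=xyz,
    )


def _roty(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def make_rigid_body_trajectory(
    toy: MolecularModel,
    slab: MolecularModel,
    schedule: AngleSchedule,
    n_frames: int = 500,
    dt_us: float = 0.01,
    tm_tilt_deg: float | Sequence[float] = 15.0,
    loop_rg: float | Sequence[float] | None = None,
    residue_z: Mapping[int, float | Sequence[float]] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    gdef: GrooveVectorDef | None = None,
    loop: LoopDefinition | None = None,
) -> tuple[Trajectory, SyntheticGroundTruth]:
    """Rigid-body trajectory with exactly prescribed descriptors.

    Per frame the soluble head (residues below the TM span) is rotated
    rigidly about an in-plane axis so the recomputed groove deviation angle
    equals the schedule value exactly; the TM helix is rotated so its
    recomputed principal axis makes exactly the prescribed tilt with +z;
    the loop is optionally rescaled about its centroid to hit a prescribed
    radius of gyration.  ``residue_z`` pins individual loop Cα atoms at
    absolute z-offsets from the upper phosphate plane (do not combine with
    ``loop_rg`` for the same frames: pinning perturbs the realized Rg).
    Gaussian coordinate noise (``noise_sd`` Å, seeded) is applied last.
    """
    gdef = gdef or GrooveVectorDef()
    loop = loop or LoopDefinition()
    rng = np.random.default_rng(seed)
    phi = schedule.sample(n_frames, dt_us, rng)
    if not ((phi > 0.0) & (phi < 180.0)).all():
        raise ConfigError("schedule produced angles outside (0, 180)")
    psi = np.broadcast_to(np.asarray(tm_tilt_deg, float), (n_frames,)).copy()
    if not ((psi > 0.0) & (psi < 180.0)).all():
        raise ConfigError("TM tilt must lie in (0, 180) degrees")

    mem = membrane_frame(slab)
    tm_first = ALPHA8.first
    head_idx = np.nonzero(toy.residue_numbers < tm_first)[0]
    tm_idx = np.nonzero(toy.residue_numbers >= tm_first)[0]
    loop_idx = toy.select(loop.selection)

    g0 = groove_vector(toy, gdef)
    r0 = _rotation_between(g0, np.array([0.0, 0.0, 1.0]))
    a_tm = helix_principal_axis(toy, ALPHA8)
    head_pivot = toy.positions[head_idx].mean(axis=0)
    tm_pivot = toy.positions[tm_idx].mean(axis=0)
    ref_rg = radius_of_gyration(toy, loop.selection)

    rg_target = None
    if loop_rg is not None:
        rg_target = np.broadcast_to(np.asarray(loop_rg, float), (n_frames,)).copy()
        if (rg_target <= 0).any():
            raise ConfigError("loop Rg targets must be positive")
    z_targets = {
        int(k): np.broadcast_to(np.asarray(v, float), (n_frames,)).copy()
        for k, v in (residue_z or {}).items()
    }
    z_pins = {}
    for resid in z_targets:
        pin = np.nonzero((toy.residue_numbers == resid) & (toy.atom_names == "CA"))[0]
        if len(pin) != 1:
            raise ConfigError(f"residue {resid} has no unique Cα to pin")
        z_pins[resid] = pin[0]

    n_protein = toy.n_atoms
    topology = merge_models(toy, slab)
    coords = np.empty((n_frames, topology.n_atoms, 3))
    for k in range(n_frames):
        xyz = toy.positions.copy()
        rh = _roty(phi[k]) @ r0
        xyz[head_idx] = (xyz[head_idx] - head_pivot) @ rh.T + head_pivot
        if rg_target is not None:
            centroid = xyz[loop_idx].mean(axis=0)
            xyz[loop_idx] = centroid + (xyz[loop_idx] - centroid) * (
                rg_target[k] / ref_rg
            )
        for resid, pin in z_pins.items():
            xyz[pin, 2] = mem.upper_plane_z + z_targets[resid][k]
        target_axis = np.array(
            [np.sin(np.radians(psi[k])), 0.0, np.cos(np.radians(psi[k]))]
        )
        rt = _rotation_between(a_tm, target_axis)
        xyz[tm_idx] = (xyz[tm_idx] - tm_pivot) @ rt.T + tm_pivot
        coords[k, :n_protein] = xyz
        coords[k, n_protein:] = slab.positions
    if noise_sd > 0:
        coords += rng.normal(0.0, noise_sd, size=coords.shape)
    traj = Trajectory(
        topology=topology, coordinates=coords, times=dt_us * np.arange(n_frames)
    )
    truth = SyntheticGroundTruth(
        groove_angle=phi,
        tm_tilt=psi,
        loop_rg=rg_target if rg_target is not None else np.full(n_frames, ref_rg),
        residue_z=z_targets,
        seed=seed,
        description=f"{schedule.kind} groove schedule, {n_frames} frames, "
        f"dt {dt_us} μs, noise {noise_sd} Å",
    )
    return traj, truth


def write_fixture(
    traj: Trajectory,
    truth: SyntheticGroundTruth,
    outdir: str | os.PathLike,
    name: str = "fixture",
) -> dict[str, str]:
    """Write a generated trajectory (multi-model PDB), its ground truth
    (TSV) and a manifest (JSON) into ``outdir``; returns the paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "trajectory": os.path.join(outdir, f"{name}.pdb"),
        "ground_truth": os.path.join(outdir, f"{name}_truth.tsv"),
        "manifest": os.path.join(outdir, f"{name}_manifest.json"),
    }
    write_trajectory(traj, paths["trajectory"])
    import pandas as pd

    table = {"time_us": traj.times, "phi_deg": truth.groove_angle,
             "psi_deg": truth.tm_tilt}
    if truth.loop_rg is not None:
        table["rg_A"] = truth.loop_rg
    for resid, z in truth.residue_z.items():
        table[f"z{resid}_A"] = z
    pd.DataFrame(table).to_csv(paths["ground_truth"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {
                "name": name,
                "n_frames": traj.n_frames,
                "n_atoms": traj.topology.n_atoms,
                "seed": truth.seed,
                "description": truth.description,
            },
            fh,
            indent=2,
        )
    return paths
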