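"""Descriptors for the long disordered α1–α2 loop.

The loop spans residues 21–81 (Gly-21 is its first residue; 61 residues in
all) and is summarized per frame by its Cα radius of gyration and by the
transmembrane z-positions of marker residues (Gly-21 near the loop start,
Gly-70 near its middle), measured against the upper phosphate plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, GrooveDynError
from .membrane_geometry import (
    DEFAULT_PHOSPHORUS_NAMES,
    membrane_frame,
    z_position,
)
from .series import TimeSeries
from .structure_io import (
    MolecularModel,
    SelectionSpec,
    Trajectory,
    require_selection,
)

__all__ = ["LoopDefinition", "radius_of_gyration", "rg_series", "residue_z_series"]


@dataclass(frozen=True)
class LoopDefinition:
    """Inclusive residue span of the loop and the atom filter used for Rg."""

    first: int = 21
    last: int = 81
    atom_name: str | None = "CA"
    chain_id: str | None = None

    @property
    def n_residues(self) -> int:
        return self.last - self.first + 1

    @property
    def selection(self) -> SelectionSpec:
        return SelectionSpec(self.first, self.last, self.atom_name, self.chain_id)


def radius_of_gyration(frame: MolecularModel, selection: SelectionSpec) -> float:
    """Unit-mass radius of gyration (Å) of the selected atoms:
    ``sqrt(mean |r_i - centroid|^2)``."""
    idx = require_selection(frame, selection)
    x = frame.positions[idx]
    x = x - x.mean(axis=0)
    return float(np.sqrt((x**2).sum(axis=1).mean()))


def rg_series(traj: Trajectory, loop: LoopDefinition | None = None) -> TimeSeries:
    """Per-frame loop radius of gyration."""
    loop = loop or LoopDefinition()
    sel = loop.selection
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        try:
            values[i] = radius_of_gyration(traj.frame(i), sel)
        except GrooveDynError as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
    return TimeSeries(times=traj.times.copy(), values=values, label="rg_A")


def residue_z_series(
    traj: Trajectory,
    residue: int,
    reference: str = "upper_plane",
    phosphorus_names=DEFAULT_PHOSPHORUS_NAMES,
) -> TimeSeries:
    """Per-frame z-position (Å) of one residue's Cα relative to the chosen
    membrane reference plane."""
    if residue < 1:
        raise ConfigError("residue number must be positive")
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        frame = traj.frame(i)
        try:
            mem = membrane_frame(frame, phosphorus_names)
            values[i] = z_position(frame, residue, mem, reference)
        except GrooveDynError as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
    return TimeSeries(times=traj.times.copy(), values=values, label=f"z{residue}_A")
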