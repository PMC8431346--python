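"""Structures, trajectories and atom selections.

The in-memory model is deliberately small: a :class:`MolecularModel` is a
flat table of atoms (names, residue identity, chain, Cartesian coordinates
in Å) and a :class:`Trajectory` is a stack of coordinate frames over one
fixed topology with strictly increasing time stamps in μs.  File I/O for the
baseline multi-model PDB dialect is delegated to :mod:`biotite`; any other
trajectory format can be adapted onto the same two classes.

Selections follow the residue-range convention used throughout the
literature on this protein: 1-based, inclusive on both ends, optionally
restricted to one atom name (typically ``CA``) and one chain.  A selection
is expressible as the string ``"chain:first-last:atomname"``.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import ConfigError, SelectionError, StructureParseError

__all__ = [
    "MolecularModel",
    "Trajectory",
    "SelectionSpec",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "resolve_selection",
    "merge_models",
]

DEFAULT_CHAIN = "A"


@dataclass
class MolecularModel:
    """One molecular configuration: a fixed-order table of atoms.

    Coordinates are in Å.  Residue numbers are 1-based and taken verbatim
    from the source file.  Atom names must be unique within a residue.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    residue_names: np.ndarray
    residue_numbers: np.ndarray
    chain_ids: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.residue_names = np.asarray(self.residue_names, dtype="U4")
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=np.int64)
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        self.positions = np.asarray(self.positions, dtype=np.float64)
        n = len(self.atom_names)
        for name in ("elements", "residue_names", "residue_numbers", "chain_ids"):
            if len(getattr(self, name)) != n:
                raise ConfigError(f"field {name!r} has length != {n}")
        if self.positions.shape != (n, 3):
            raise ConfigError(
                f"positions must have shape ({n}, 3), got {self.positions.shape}"
            )
        if n and self.residue_numbers.min() < 1:
            raise ConfigError("residue numbers must be strictly positive")
        if not np.isfinite(self.positions).all():
            raise ConfigError("positions must be finite")
        seen = set()
        for key in zip(self.chain_ids, self.residue_numbers, self.atom_names):
            if key in seen:
                raise ConfigError(
                    f"duplicate atom name {key[2]!r} in residue "
                    f"{key[0]}:{key[1]} — atom names must be unique per residue"
                )
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def copy(self) -> "MolecularModel":
        return MolecularModel(
            self.atom_names.copy(),
            self.elements.copy(),
            self.residue_names.copy(),
            self.residue_numbers.copy(),
            self.chain_ids.copy(),
            self.positions.copy(),
        )

    def with_positions(self, positions: np.ndarray) -> "MolecularModel":
        """Same topology, new coordinates (no validation re-run on metadata)."""
        out = dataclasses.replace(self, positions=np.asarray(positions, float))
        return out

    def transformed(
        self, rotation: np.ndarray | None = None, translation: np.ndarray | None = None
    ) -> "MolecularModel":
        """Apply a rigid transform x -> R x + t and return a new model."""
        xyz = self.positions
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation, float).T
        if translation is not None:
            xyz = xyz + np.asarray(translation, float)
        return self.with_positions(xyz)

    def select(self, spec: "SelectionSpec") -> np.ndarray:
        return resolve_selection(self, spec)

    def subset(self, indices: np.ndarray) -> "MolecularModel":
        idx = np.asarray(indices, dtype=np.int64)
        return MolecularModel(
            self.atom_names[idx],
            self.elements[idx],
            self.residue_names[idx],
            self.residue_numbers[idx],
            self.chain_ids[idx],
            self.positions[idx],
        )


@dataclass(frozen=True)
class SelectionSpec:
    """Inclusive residue range + optional atom-name and chain filters.

    ``atom_name=None`` keeps all atoms of the residues; ``chain_id=None``
    matches every chain.  ``"A:143-146:CA"`` parses to
    ``SelectionSpec(143, 146, "CA", "A")``.
    """

    first: int
    last: int
    atom_name: str | None = "CA"
    chain_id: str | None = None

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ConfigError(
                f"selection range first ({self.first}) > last ({self.last})"
            )

    @classmethod
    def from_string(cls, text: str) -> "SelectionSpec":
        parts = text.strip().split(":")
        if len(parts) != 3:
            raise ConfigError(
                f"selection string {text!r} must look like 'chain:first-last:atomname'"
            )
        chain, rng, name = parts
        try:
            first_s, last_s = rng.split("-")
            first, last = int(first_s), int(last_s)
        except ValueError as exc:
            raise ConfigError(f"bad residue range in selection {text!r}") from exc
        return cls(
            first=first,
            last=last,
            atom_name=name if name not in ("", "*") else None,
            chain_id=chain if chain not in ("", "*") else None,
        )

    def __str__(self) -> str:
        return (
            f"{self.chain_id or '*'}:{self.first}-{self.last}:{self.atom_name or '*'}"
        )


def resolve_selection(model: MolecularModel, spec: SelectionSpec) -> np.ndarray:
    """Indices (in model order) of atoms matching ``spec``.

    Returns an empty array for an empty match; callers that require atoms
    should use :func:`require_selection`.
    """
    mask = (model.residue_numbers >= spec.first) & (model.residue_numbers <= spec.last)
    if spec.atom_name is not None:
        mask &= model.atom_names == spec.atom_name
    if spec.chain_id is not None:
        mask &= model.chain_ids == spec.chain_id
    return np.nonzero(mask)[0]


def require_selection(
    model: MolecularModel, spec: SelectionSpec, minimum: int = 1
) -> np.ndarray:
    idx = resolve_selection(model, spec)
    if len(idx) < minimum:
        raise SelectionError(
            f"selection {spec} resolved to {len(idx)} atoms "
            f"(need at least {minimum})"
        )
    return idx


@dataclass
class Trajectory:
    """Ordered coordinate frames over one topology.

    ``coordinates`` has shape (n_frames, n_atoms, 3) in Å; ``times`` are in
    μs and strictly increasing; ``box`` is an optional per-frame 3-vector of
    orthorhombic cell lengths.
    """

    topology: MolecularModel
    coordinates: np.ndarray
    times: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ConfigError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ConfigError(
                f"coordinate frames have {self.coordinates.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}"
            )
        if len(self.times) != self.coordinates.shape[0]:
            raise ConfigError("times length must equal frame count")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ConfigError("frame times must be strictly increasing")
        if not np.isfinite(self.coordinates).all():
            raise ConfigError("trajectory coordinates must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=np.float64)
            if self.box.shape != (len(self.times), 3):
                raise ConfigError("box must have shape (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> MolecularModel:
        """Frame ``i`` as a standalone :class:`MolecularModel`."""
        return self.topology.with_positions(self.coordinates[i])

    def __iter__(self) -> Iterator[MolecularModel]:
        for i in range(self.n_frames):
            yield self.frame(i)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------


def _to_atom_array(model: MolecularModel) -> struc.AtomArray:
    arr = struc.AtomArray(model.n_atoms)
    arr.coord = model.positions.astype(np.float32)
    arr.chain_id = model.chain_ids
    arr.res_id = model.residue_numbers
    arr.res_name = model.residue_names
    arr.atom_name = model.atom_names
    arr.element = model.elements
    arr.set_annotation("hetero", np.zeros(model.n_atoms, dtype=bool))
    return arr


def _from_atom_array(arr: struc.AtomArray) -> MolecularModel:
    chains = np.asarray(arr.chain_id, dtype="U4")
    chains = np.where(np.char.strip(chains) == "", DEFAULT_CHAIN, chains)
    return MolecularModel(
        atom_names=np.asarray(arr.atom_name),
        elements=np.asarray(arr.element),
        residue_names=np.asarray(arr.res_name),
        residue_numbers=np.asarray(arr.res_id, dtype=np.int64),
        chain_ids=chains,
        positions=np.asarray(arr.coord, dtype=np.float64),
    )


def read_structure(path: str | os.PathLike, format: str = "pdb") -> MolecularModel:
    """Read a single-configuration structure file (first model if several)."""
    if format.lower() != "pdb":
        raise ConfigError(f"unsupported structure format {format!r}")
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
    except Exception as exc:  # biotite raises various subclasses
        raise StructureParseError(f"failed to parse {path}: {exc}") from exc
    if np.isnan(np.asarray(arr.coord, float)).any():
        raise StructureParseError(f"{path}: missing coordinates")
    return _from_atom_array(arr)


def write_structure(model: MolecularModel, path: str | os.PathLike) -> None:
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(model))
    pdb.write(str(path))


def read_trajectory(
    path: str | os.PathLike,
    format: str = "pdb",
    dt_us: float = 0.01,
    t0_us: float = 0.0,
    times: Sequence[float] | None = None,
) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    PDB carries no time axis, so frame times are assigned from the config:
    either an explicit ``times`` sequence (μs) or ``t0_us + i * dt_us``.
    """
    if format.lower() != "pdb":
        raise ConfigError(f"unsupported trajectory format {format!r}")
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:
        raise StructureParseError(f"failed to parse trajectory {path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):  # single MODEL
        stack = struc.stack([stack])
    topology = _from_atom_array(stack[0])
    coords = np.asarray(stack.coord, dtype=np.float64)
    n = coords.shape[0]
    if times is not None:
        t = np.asarray(list(times), dtype=np.float64)
        if len(t) != n:
            raise ConfigError(f"{len(t)} times supplied for {n} frames")
    else:
        t = t0_us + dt_us * np.arange(n)
    return Trajectory(topology=topology, coordinates=coords, times=t)


def write_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write as multi-model PDB (one MODEL per frame; times are not stored)."""
    arrays = []
    for i in range(traj.n_frames):
        arr = _to_atom_array(traj.topology)
        arr.coord = traj.coordinates[i].astype(np.float32)
        arrays.append(arr)
    pdb = PDBFile()
    pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))


def merge_models(*models: MolecularModel) -> MolecularModel:
    """Concatenate atom tables (e.g. protein + membrane slab)."""
    return MolecularModel(
        np.concatenate([m.atom_names for m in models]),
        np.concatenate([m.elements for m in models]),
        np.concatenate([m.residue_names for m in models]),
        np.concatenate([m.residue_numbers for m in models]),
        np.concatenate([m.chain_ids for m in models]),
        np.concatenate([m.positions for m in models]),
    )
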