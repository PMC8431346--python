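"""Construction of the full-length membrane-anchored model.

The anchored model is a chimera of two experimental structures: a soluble
head (residues 1–222, lacking the anchor helix) and an isolated C-terminal
helix α8 (residues 209–231).  The build is three rigid-body steps, in the
order they are applied:

1. :func:`align_helix_to_z` — rotate the tail so the α8 principal axis lies
   exactly along +z (the membrane normal of a planar bilayer).
2. :func:`join_structures` — least-squares superpose the head onto the tail
   over the Cα atoms of the overlap window around the junction (Gln-207;
   default window 207–214) and keep residues ≤ 207 from the head and > 207
   from the tail, as a single chain.
3. :func:`embed_in_membrane` — translate the chimera along z so that the
   anchor tryptophan (Trp-213) Cα sits just below the upper phosphate
   plane, the head approaches within 4 Å of the membrane surface, and the
   TM helix spans both phosphate planes.

Every step is rigid (pairwise distances preserved) and deterministic; no
minimization or remodeling is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigError, ConstraintError
from .groove_geometry import ALPHA8, HelixDefinition, helix_principal_axis
from .membrane_geometry import MembraneFrame
from .structure_io import (
    MolecularModel,
    SelectionSpec,
    merge_models,
    require_selection,
)

__all__ = [
    "JoinSpec",
    "EmbeddingSpec",
    "align_helix_to_z",
    "superpose",
    "join_structures",
    "embed_in_membrane",
    "embedding_report",
]


@dataclass
class JoinSpec:
    """How to splice the soluble head onto the membrane-anchor tail."""

    head_model: MolecularModel
    tail_model: MolecularModel
    junction_residue: int = 207
    superposition_selection: SelectionSpec = field(
        default_factory=lambda: SelectionSpec(207, 214, "CA")
    )
    rmsd_warn_threshold: float = 3.0  # Å; the two source structures differ

    def __post_init__(self) -> None:
        head_res = self.head_model.residue_numbers
        if not (head_res.min() <= self.junction_residue <= head_res.max()):
            raise ConfigError(
                f"junction residue {self.junction_residue} outside head range "
                f"{head_res.min()}–{head_res.max()}"
            )


@dataclass(frozen=True)
class EmbeddingSpec:
    """Depth constraints for anchoring the chimera at the bilayer.

    ``anchor_depth`` is how far below the upper phosphate plane the anchor
    residue's Cα may sit ("just below the phosphates"); ``max_head_gap`` is
    the maximum allowed gap between the soluble head and the membrane
    surface (the upper phosphate plane).
    """

    anchor_residue: int = 213
    anchor_depth: float = 3.0
    max_head_gap: float = 4.0
    head_range: tuple[int, int] = (1, 207)
    tm_helix: HelixDefinition = ALPHA8

    def __post_init__(self) -> None:
        if self.anchor_depth <= 0 or self.max_head_gap <= 0:
            raise ConfigError("anchor_depth and max_head_gap must be positive")


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector ``a`` exactly onto unit vector
    ``b`` (about their mutual perpendicular)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    cross = np.cross(a, b)
    norm = np.linalg.norm(cross)
    dot = float(np.clip(a @ b, -1.0, 1.0))
    if norm < 1e-12:
        if dot > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return Rotation.from_rotvec(np.pi * perp).as_matrix()
    axis = cross / norm
    return Rotation.from_rotvec(axis * np.arccos(dot)).as_matrix()


def align_helix_to_z(
    model: MolecularModel,
    helix: HelixDefinition | SelectionSpec,
    direction: str = "+z",
) -> MolecularModel:
    """Rotate the whole model (about the helix Cα centroid) so the helix
    principal axis lies along z.

    ``direction`` chooses where the N→C axis ends up: ``"+z"`` (default) or
    ``"-z"``.  A transmembrane anchor whose N-terminal end must face the
    soluble head above the membrane is aligned with ``"-z"``.
    """
    if direction not in ("+z", "-z"):
        raise ConfigError("direction must be '+z' or '-z'")
    if isinstance(helix, SelectionSpec):
        helix = HelixDefinition("helix", helix.first, helix.last, helix.chain_id)
    axis = helix_principal_axis(model, helix)
    target = np.array([0.0, 0.0, 1.0 if direction == "+z" else -1.0])
    rot = _rotation_between(axis, target)
    idx = require_selection(model, helix.selection, minimum=3)
    pivot = model.positions[idx].mean(axis=0)
    return model.transformed(rot, pivot - rot @ pivot)


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of point sets.

    Returns ``(R, t, rmsd)`` with ``R x + t`` mapping mobile onto reference.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise ConfigError("point sets must have identical (N, 3) shapes")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    r = rot.as_matrix()
    t = ref_c - r @ mob_c
    rmsd = float(rssd / np.sqrt(len(mobile)))
    return r, t, rmsd


def join_structures(spec: JoinSpec) -> tuple[MolecularModel, float]:
    """Splice head and tail into a single-chain chimera.

    The head is superposed onto the tail over the Cα atoms of the overlap
    selection; residues ≤ junction come from the (transformed) head,
    residues > junction from the tail.  Returns the chimera and the fit
    RMSD (Å); a large RMSD warns rather than fails, since the two source
    structures are independent experimental models.
    """
    sel = spec.superposition_selection
    head_idx = require_selection(spec.head_model, sel, minimum=3)
    tail_idx = require_selection(spec.tail_model, sel, minimum=3)
    # pair atoms on the residues both sources actually cover inside the
    # overlap window (the two deposited constructs span different ranges)
    head_map = {
        (r, a): i
        for r, a, i in zip(
            spec.head_model.residue_numbers[head_idx],
            spec.head_model.atom_names[head_idx],
            head_idx,
        )
    }
    pairs = [
        (head_map[(r, a)], i)
        for r, a, i in zip(
            spec.tail_model.residue_numbers[tail_idx],
            spec.tail_model.atom_names[tail_idx],
            tail_idx,
        )
        if (r, a) in head_map
    ]
    if len(pairs) < 3:
        raise ConfigError(
            f"overlap selection {sel} shares only {len(pairs)} atoms between "
            "head and tail (need at least 3)"
        )
    head_common = np.array([p[0] for p in pairs])
    tail_common = np.array([p[1] for p in pairs])
    r, t, rmsd = superpose(
        spec.head_model.positions[head_common],
        spec.tail_model.positions[tail_common],
    )
    if rmsd > spec.rmsd_warn_threshold:
        warnings.warn(
            f"overlap fit RMSD {rmsd:.2f} Å exceeds {spec.rmsd_warn_threshold} Å",
            stacklevel=2,
        )
    head = spec.head_model.transformed(r, t)
    head_part = head.subset(
        np.nonzero(head.residue_numbers <= spec.junction_residue)[0]
    )
    tail_part = spec.tail_model.subset(
        np.nonzero(spec.tail_model.residue_numbers > spec.junction_residue)[0]
    )
    chimera = merge_models(head_part, tail_part)
    chimera.chain_ids[:] = "A"
    return chimera, rmsd


def _constraints(
    model: MolecularModel, membrane: MembraneFrame, spec: EmbeddingSpec
) -> dict[str, float]:
    anchor = require_selection(
        model, SelectionSpec(spec.anchor_residue, spec.anchor_residue, "CA")
    )
    anchor_z = float(model.positions[anchor, 2].mean())
    head_sel = SelectionSpec(*spec.head_range, atom_name=None)
    head_idx = require_selection(model, head_sel)
    head_gap = float(
        np.abs(model.positions[head_idx, 2] - membrane.upper_plane_z).min()
    )
    tm_idx = require_selection(model, spec.tm_helix.selection, minimum=3)
    tm_z = model.positions[tm_idx, 2]
    return {
        "anchor_z": anchor_z,
        "anchor_depth": membrane.upper_plane_z - anchor_z,
        "head_gap": head_gap,
        "tm_top_z": float(tm_z.max()),
        "tm_bottom_z": float(tm_z.min()),
    }


def _violations(
    values: dict[str, float], membrane: MembraneFrame, spec: EmbeddingSpec
) -> list[str]:
    out = []
    if not (0.0 < values["anchor_depth"] <= spec.anchor_depth):
        out.append(
            f"anchor residue {spec.anchor_residue} Cα is "
            f"{values['anchor_depth']:.2f} Å below the upper phosphate plane "
            f"(need within (0, {spec.anchor_depth}] Å)"
        )
    if values["head_gap"] > spec.max_head_gap:
        out.append(
            f"head–membrane gap {values['head_gap']:.2f} Å exceeds "
            f"{spec.max_head_gap} Å"
        )
    if values["tm_top_z"] < membrane.upper_plane_z or (
        values["tm_bottom_z"] > membrane.lower_plane_z
    ):
        out.append("TM helix does not span both phosphate planes")
    return out


def embed_in_membrane(
    model: MolecularModel,
    membrane: MembraneFrame,
    spec: EmbeddingSpec | None = None,
) -> MolecularModel:
    """Rigid z-translation placing the chimera at the bilayer.

    Scans anchor depths within ``(0, anchor_depth]`` and returns the
    placement closest to the band midpoint that satisfies every constraint;
    raises :class:`ConstraintError` naming the violated constraints if none
    exists (e.g. the plane gap exceeds the TM helix length).
    """
    spec = spec or EmbeddingSpec()
    anchor = require_selection(
        model, SelectionSpec(spec.anchor_residue, spec.anchor_residue, "CA")
    )
    anchor_z = float(model.positions[anchor, 2].mean())
    nominal_depth = 0.5 * spec.anchor_depth
    depths = np.unique(
        np.concatenate(
            [[nominal_depth], np.linspace(0.05, spec.anchor_depth, 60)]
        )
    )
    depths = depths[np.argsort(np.abs(depths - nominal_depth))]
    first_violation: list[str] | None = None
    for depth in depths:
        shift = (membrane.upper_plane_z - depth) - anchor_z
        candidate = model.transformed(None, np.array([0.0, 0.0, shift]))
        bad = _violations(_constraints(candidate, membrane, spec), membrane, spec)
        if not bad:
            return candidate
        if first_violation is None:
            first_violation = bad
    raise ConstraintError(
        "membrane embedding infeasible; at the nominal depth: "
        + "; ".join(first_violation or ["unknown"])
    )


def embedding_report(
    model: MolecularModel, membrane: MembraneFrame, spec: EmbeddingSpec | None = None
) -> dict[str, float]:
    """Constraint values of an embedded model (for build reports)."""
    spec = spec or EmbeddingSpec()
    values = _constraints(model, membrane, spec)
    values["upper_plane_z"] = membrane.upper_plane_z
    values["lower_plane_z"] = membrane.lower_plane_z
    return values
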