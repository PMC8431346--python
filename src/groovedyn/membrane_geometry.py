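"""The per-frame membrane reference frame.

A planar bilayer is summarized by its two phosphate planes: the arithmetic
mean z of the lipid phosphorus atoms in each leaflet.  The membrane normal
is the simulation-box z axis (the bilayers analysed here are planar and
assembled normal to z), oriented toward the leaflet facing the protein's
soluble head.  Leaflets are assigned by the sign of ``z − median(P z)``,
which is robust for planar bilayers without any clustering.

Insertion depths are signed distances along the normal from a chosen
reference surface (upper phosphate plane by default, midplane optionally);
positive values point away from the membrane into the solvent on the head
side, matching how z-distributions of loop residues are usually drawn.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, DegenerateGeometryError, SelectionError
from .structure_io import MolecularModel, SelectionSpec, require_selection

__all__ = ["MembraneFrame", "membrane_frame", "z_position"]

DEFAULT_PHOSPHORUS_NAMES = ("P",)


@dataclass(frozen=True)
class MembraneFrame:
    """Unit membrane normal and per-leaflet mean phosphate-plane z (Å)."""

    normal: np.ndarray
    upper_plane_z: float
    lower_plane_z: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "normal", np.asarray(self.normal, dtype=np.float64))
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ConfigError("membrane normal must be a unit vector")
        if not self.upper_plane_z > self.lower_plane_z:
            raise ConfigError("upper_plane_z must exceed lower_plane_z")

    @property
    def midplane_z(self) -> float:
        return 0.5 * (self.upper_plane_z + self.lower_plane_z)

    def reference_z(self, reference: str) -> float:
        if reference == "upper_plane":
            return self.upper_plane_z
        if reference == "lower_plane":
            return self.lower_plane_z
        if reference == "midplane":
            return self.midplane_z
        raise ConfigError(
            f"reference must be 'upper_plane', 'lower_plane' or 'midplane', "
            f"got {reference!r}"
        )


def membrane_frame(
    frame: MolecularModel,
    phosphorus_names: Sequence[str] = DEFAULT_PHOSPHORUS_NAMES,
    head_z: float | None = None,
) -> MembraneFrame:
    """Phosphate planes and membrane normal for one frame.

    ``head_z`` (e.g. the soluble-head centroid z) orients the normal toward
    the head-facing leaflet; by default the normal is +z.
    """
    mask = np.isin(frame.atom_names, list(phosphorus_names))
    z = frame.positions[mask, 2]
    if z.size == 0:
        raise SelectionError(
            f"no phosphorus atoms named {tuple(phosphorus_names)} in frame"
        )
    median = float(np.median(z))
    upper = z[z >= median]
    lower = z[z < median]
    if upper.size == 0 or lower.size == 0:
        raise DegenerateGeometryError(
            "all phosphorus atoms fall in a single leaflet; cannot define two "
            "phosphate planes"
        )
    normal = np.array([0.0, 0.0, 1.0])
    if head_z is not None and head_z < median:
        normal = -normal
    return MembraneFrame(
        normal=normal,
        upper_plane_z=float(upper.mean()),
        lower_plane_z=float(lower.mean()),
    )


def z_position(
    frame: MolecularModel,
    selection: SelectionSpec | int,
    membrane: MembraneFrame,
    reference: str = "upper_plane",
) -> float:
    """Signed distance (Å) along the membrane normal from the reference
    plane to the selection centroid.

    An integer selects that residue's Cα.  Positive values lie on the side
    the normal points to (the solvent on the head side).
    """
    if isinstance(selection, (int, np.integer)):
        selection = SelectionSpec(int(selection), int(selection), atom_name="CA")
    idx = require_selection(frame, selection)
    centroid_z = float(frame.positions[idx, 2].mean())
    return float((centroid_z - membrane.reference_z(reference)) * membrane.normal[2])
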