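"""Orientation descriptors for the membrane-anchored conformation.

Two angles, both measured against the membrane normal, summarize each
trajectory frame:

* the BH3-binding-groove deviation angle ϕ — the angle between the membrane
  normal and the groove vector ``g = unit(a × c)``, where ``a`` is the
  principal axis of helix α5 (residues 143–153) and ``c`` connects the
  geometric center of the Cα atoms of residues 143–146 (α5) to that of
  residues 170–173 (α6).  Angles above 90° indicate a partially occluded
  groove (facing the membrane), below 90° a more accessible one.
* the TM-helix tilt ψ — the angle between the membrane normal and the
  principal axis of the anchor helix α8 (residues 209–231).

A helix principal axis is the eigenvector of the moment-of-inertia tensor
of the helix Cα atoms (unit masses, taken about their centroid) with the
smallest eigenvalue, i.e. the long axis, sign-fixed to point N→C.  Helix
residue memberships are fixed once from the initial configuration; the axis
itself is recomputed on every frame (set ``frozen_axis=True`` on the series
functions to instead freeze the axis at frame 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DegenerateGeometryError, GrooveDynError
from .membrane_geometry import (
    DEFAULT_PHOSPHORUS_NAMES,
    MembraneFrame,
    membrane_frame,
)
from .series import AngleSeries
from .structure_io import (
    MolecularModel,
    SelectionSpec,
    Trajectory,
    require_selection,
)

__all__ = [
    "HelixDefinition",
    "GrooveVectorDef",
    "ALPHA5",
    "ALPHA8",
    "inertia_tensor",
    "helix_principal_axis",
    "groove_vector",
    "deviation_angle",
    "classify_accessibility",
    "groove_angle_series",
    "tm_tilt_series",
]

#: relative eigenvalue-gap threshold below which the long axis is ambiguous
DEGENERACY_RTOL = 1e-9


@dataclass(frozen=True)
class HelixDefinition:
    """A helix as an inclusive Cα residue span; axis sign is N→C."""

    label: str
    first: int
    last: int
    chain_id: str | None = None

    def __post_init__(self) -> None:
        if self.last - self.first + 1 < 3:
            raise ConfigError(
                f"helix {self.label!r} span {self.first}-{self.last} has fewer "
                "than 3 residues"
            )

    @property
    def selection(self) -> SelectionSpec:
        return SelectionSpec(self.first, self.last, "CA", self.chain_id)


ALPHA5 = HelixDefinition("alpha5", 143, 153)
ALPHA8 = HelixDefinition("alpha8", 209, 231)


@dataclass(frozen=True)
class GrooveVectorDef:
    """Residue spans defining the groove vector, with the sign convention.

    ``flip=True`` reverses the cross-product order, mapping every deviation
    angle ϕ onto 180° − ϕ (a documented involution; the occluded/accessible
    semantics of the default orientation place angles > 90° on the
    membrane-facing side).
    """

    alpha5: HelixDefinition = ALPHA5
    alpha5_center: SelectionSpec = field(
        default_factory=lambda: SelectionSpec(143, 146, "CA")
    )
    alpha6_center: SelectionSpec = field(
        default_factory=lambda: SelectionSpec(170, 173, "CA")
    )
    flip: bool = False


def inertia_tensor(points: np.ndarray) -> np.ndarray:
    """Moment-of-inertia tensor of unit-mass points about their centroid."""
    x = np.asarray(points, dtype=np.float64)
    x = x - x.mean(axis=0)
    r2 = (x**2).sum(axis=1)
    return np.eye(3) * r2.sum() - x.T @ x


def helix_principal_axis(
    frame: MolecularModel, helix: HelixDefinition
) -> np.ndarray:
    """Unit long-axis of a helix from its Cα inertia tensor, pointing N→C.

    Raises :class:`DegenerateGeometryError` when the two smallest inertia
    eigenvalues are relatively closer than ``DEGENERACY_RTOL`` (no unique
    long axis) or fewer than 3 Cα resolve.
    """
    idx = require_selection(frame, helix.selection, minimum=3)
    points = frame.positions[idx]
    tensor = inertia_tensor(points)
    eigval, eigvec = np.linalg.eigh(tensor)  # ascending eigenvalues
    scale = max(abs(eigval[-1]), 1.0)
    if (eigval[1] - eigval[0]) / scale < DEGENERACY_RTOL:
        raise DegenerateGeometryError(
            f"helix {helix.label!r}: inertia eigenvalues {eigval[0]:.6g} and "
            f"{eigval[1]:.6g} are degenerate; long axis undefined"
        )
    axis = eigvec[:, 0]
    n_to_c = points[-1] - points[0]
    if float(axis @ n_to_c) < 0.0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _center(frame: MolecularModel, spec: SelectionSpec) -> np.ndarray:
    idx = require_selection(frame, spec)
    return frame.positions[idx].mean(axis=0)


def groove_vector(frame: MolecularModel, gdef: GrooveVectorDef | None = None) -> np.ndarray:
    """Unit normal of the plane spanned by the α5 axis and the α5→α6
    inter-helix connector."""
    gdef = gdef or GrooveVectorDef()
    a = helix_principal_axis(frame, gdef.alpha5)
    c = _center(frame, gdef.alpha6_center) - _center(frame, gdef.alpha5_center)
    g = np.cross(c, a) if gdef.flip else np.cross(a, c)
    norm = np.linalg.norm(g)
    if norm < 1e-6 * np.linalg.norm(c):
        raise DegenerateGeometryError(
            "helix axis and inter-helix connector are collinear; groove plane "
            "undefined"
        )
    return g / norm


def deviation_angle(v: np.ndarray, membrane: MembraneFrame) -> float:
    """Angle (degrees, in [0, 180]) between a unit vector and the membrane
    normal."""
    v = np.asarray(v, dtype=np.float64)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise ConfigError("cannot take the deviation angle of a zero vector")
    cosang = float(np.clip(v @ membrane.normal / norm, -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def classify_accessibility(angle: float) -> str:
    """'accessible' below 90°, 'occluded' at or above (boundary counted as
    occluded, the conservative choice).  Angles within 1e-9° of the
    boundary are treated as exactly 90° so floating-point noise cannot
    flip the class."""
    if not 0.0 <= angle <= 180.0:
        raise ConfigError(f"deviation angle {angle} outside [0, 180]")
    return "accessible" if angle < 90.0 - 1e-9 else "occluded"


def _series(
    traj: Trajectory,
    vector_of_frame,
    phosphorus_names,
    label: str,
) -> AngleSeries:
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        frame = traj.frame(i)
        try:
            mem = membrane_frame(frame, phosphorus_names)
            values[i] = deviation_angle(vector_of_frame(frame, i), mem)
        except GrooveDynError as exc:
            raise type(exc)(f"frame {i} (t={traj.times[i]:g} μs): {exc}") from exc
    return AngleSeries(times=traj.times.copy(), values=values, label=label)


def groove_angle_series(
    traj: Trajectory,
    gdef: GrooveVectorDef | None = None,
    phosphorus_names=DEFAULT_PHOSPHORUS_NAMES,
    frozen_axis: bool = False,
) -> AngleSeries:
    """ϕ(t): groove-vector deviation angle for every frame."""
    gdef = gdef or GrooveVectorDef()
    if frozen_axis:
        g0 = groove_vector(traj.frame(0), gdef)
        return _series(traj, lambda f, i: g0, phosphorus_names, "phi_deg")
    return _series(traj, lambda f, i: groove_vector(f, gdef), phosphorus_names, "phi_deg")


def tm_tilt_series(
    traj: Trajectory,
    helix: HelixDefinition = ALPHA8,
    phosphorus_names=DEFAULT_PHOSPHORUS_NAMES,
    frozen_axis: bool = False,
) -> AngleSeries:
    """ψ(t): TM-helix principal-axis deviation angle for every frame."""
    if frozen_axis:
        a0 = helix_principal_axis(traj.frame(0), helix)
        return _series(traj, lambda f, i: a0, phosphorus_names, "psi_deg")
    return _series(
        traj, lambda f, i: helix_principal_axis(f, helix), phosphorus_names, "psi_deg"
    )
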