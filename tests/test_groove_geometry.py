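import numpy as np
import pytest

from conftest import random_rotation
from groovedyn import (
    ALPHA5,
    ALPHA8,
    ConfigError,
    DegenerateGeometryError,
    GrooveVectorDef,
    HelixDefinition,
    MembraneFrame,
    MolecularModel,
    classify_accessibility,
    deviation_angle,
    groove_angle_series,
    groove_vector,
    helix_principal_axis,
    make_ideal_helix,
    tm_tilt_series,
)
from groovedyn.groove_geometry import inertia_tensor

MEM = MembraneFrame(np.array([0.0, 0.0, 1.0]), 15.0, -15.0)


def bruteforce_long_axis(points: np.ndarray) -> np.ndarray:
    """Independent oracle: inertia tensor assembled by explicit per-point
    summation, eigendecomposed with numpy.linalg.eig, smallest eigenvalue,
    same N→C sign rule."""
    centroid = points.mean(axis=0)
    tensor = np.zeros((3, 3))
    for p in points:
        d = p - centroid
        for i in range(3):
            for j in range(3):
                tensor[i, j] += (d @ d if i == j else 0.0) - d[i] * d[j]
    eigval, eigvec = np.linalg.eig(tensor)
    axis = np.real(eigvec[:, np.argmin(np.real(eigval))])
    if axis @ (points[-1] - points[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def ca_model(points: np.ndarray, start: int = 143) -> MolecularModel:
    n = len(points)
    return MolecularModel(
        np.full(n, "CA"), np.full(n, "C"), np.full(n, "ALA"),
        start + np.arange(n), np.full(n, "A"), points,
    )


def test_ideal_helix_axis_is_z():
    helix = make_ideal_helix(11, start_residue=143)
    axis = helix_principal_axis(helix, ALPHA5)
    np.testing.assert_allclose(axis, [0.0, 0.0, 1.0], atol=1e-6)


def test_rotated_helix_axis_follows_rotation():
    rng = np.random.default_rng(5)
    helix = make_ideal_helix(11, start_residue=143)
    for _ in range(20):
        rot = random_rotation(rng)
        rotated = helix.transformed(rot)
        axis = helix_principal_axis(rotated, ALPHA5)
        expect = bruteforce_long_axis(rotated.positions)
        np.testing.assert_allclose(axis, expect, atol=1e-9)
        np.testing.assert_allclose(axis, rot @ [0.0, 0.0, 1.0], atol=1e-6)


def test_n_to_c_sign_convention():
    down = make_ideal_helix(11, start_residue=143, n_to_c="down")
    axis = helix_principal_axis(down, ALPHA5)
    np.testing.assert_allclose(axis, [0.0, 0.0, -1.0], atol=1e-6)


def test_principal_axis_matches_bruteforce_on_random_point_sets():
    rng = np.random.default_rng(42)
    for _ in range(100):
        points = rng.standard_normal((rng.integers(4, 30), 3)) * [5.0, 1.0, 1.0]
        points = points @ random_rotation(rng).T
        model = ca_model(points)
        helix = HelixDefinition("h", 143, 143 + len(points) - 1)
        np.testing.assert_allclose(
            helix_principal_axis(model, helix),
            bruteforce_long_axis(points),
            atol=1e-9,
        )


def test_too_few_or_degenerate_points_raise():
    from groovedyn.errors import SelectionError

    with pytest.raises(SelectionError):
        helix_principal_axis(ca_model(np.eye(3)[:2]), HelixDefinition("h", 143, 153))
    # perfectly spherical point set: no unique long axis
    sphere = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1.0]]
    )
    with pytest.raises(DegenerateGeometryError):
        helix_principal_axis(ca_model(sphere), HelixDefinition("h", 143, 148))


def test_inertia_tensor_translation_invariant():
    rng = np.random.default_rng(2)
    points = rng.standard_normal((10, 3))
    np.testing.assert_allclose(
        inertia_tensor(points), inertia_tensor(points + [10.0, -4.0, 7.0]), atol=1e-9
    )


def toy_groove_model(a_dir, c_dir, start_axis=143):
    """α5 along ``a_dir`` plus a 4-Cα block offset by ``c_dir`` standing in
    for the α6 center residues."""
    from groovedyn import merge_models
    from groovedyn.model_builder import _rotation_between

    rot = _rotation_between(np.array([0.0, 0.0, 1.0]), np.asarray(a_dir, float))
    helix5 = make_ideal_helix(11, start_residue=143, rotation=rot)
    block = ca_model(
        np.asarray(c_dir, float) * 12.0 + 0.1 * np.arange(4)[:, None] * [1.0, 0, 0],
        start=170,
    )
    return merge_models(helix5, block)


def test_groove_vector_is_cross_product():
    # α5 axis ≈ +z, connector ≈ +x  =>  g = z × x = +y
    model = toy_groove_model([0, 0, 1.0], [1.0, 0, 0])
    g = groove_vector(model)
    assert g[1] > 0.99


def test_groove_vector_equivariance_under_rotation():
    rng = np.random.default_rng(9)
    model = toy_groove_model([0, 0, 1.0], [1.0, 0.2, 0])
    g = groove_vector(model)
    for _ in range(25):
        rot = random_rotation(rng)
        np.testing.assert_allclose(
            groove_vector(model.transformed(rot)), rot @ g, atol=1e-9
        )


def test_collinear_connector_raises():
    from groovedyn import SelectionSpec, merge_models

    helix5 = make_ideal_helix(11, start_residue=143)
    axis = helix_principal_axis(helix5, ALPHA5)
    c0 = helix5.positions[helix5.select(SelectionSpec(143, 146, "CA"))].mean(axis=0)
    # place the α6-center block exactly along the α5 axis from the α5 center
    block = ca_model(c0 + axis * (12.0 + 0.1 * np.arange(4))[:, None], start=170)
    with pytest.raises(DegenerateGeometryError):
        groove_vector(merge_models(helix5, block))


@pytest.mark.parametrize(
    "v,expected",
    [([0, 0, 1.0], 0.0), ([1.0, 0, 0], 90.0), ([0, 0, -1.0], 180.0)],
)
def test_deviation_angle_closed_forms(v, expected):
    assert deviation_angle(np.array(v), MEM) == pytest.approx(expected, abs=1e-9)


def test_deviation_angle_rejects_zero_vector():
    with pytest.raises(ConfigError):
        deviation_angle(np.zeros(3), MEM)


@pytest.mark.parametrize(
    "angle,label",
    [(100.0, "occluded"), (40.0, "accessible"), (90.0, "occluded"),
     (89.999, "accessible")],
)
def test_accessibility_classification(angle, label):
    assert classify_accessibility(angle) == label


def test_accessibility_rejects_out_of_range():
    with pytest.raises(ConfigError):
        classify_accessibility(190.0)


def test_series_recovery_matches_schedule(piecewise_run):
    traj, truth = piecewise_run
    phi = groove_angle_series(traj)
    np.testing.assert_allclose(phi.values, truth.groove_angle, atol=1e-6)
    psi = tm_tilt_series(traj)
    np.testing.assert_allclose(psi.values, truth.tm_tilt, atol=1e-6)


def test_static_trajectory_gives_constant_series(toy, slab):
    from groovedyn import AngleSchedule, make_rigid_body_trajectory

    traj, _ = make_rigid_body_trajectory(
        toy, slab, AngleSchedule("constant", levels=[97.0]), n_frames=10
    )
    phi = groove_angle_series(traj)
    assert np.ptp(phi.values) < 1e-9


def test_rotation_about_membrane_normal_leaves_angles_invariant(piecewise_run):
    from groovedyn import Trajectory

    traj, truth = piecewise_run
    rng = np.random.default_rng(3)
    coords = traj.coordinates.copy()
    for k in range(traj.n_frames):
        theta = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        rot_z = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        coords[k] = coords[k] @ rot_z.T
    spun = Trajectory(traj.topology, coords, traj.times)
    np.testing.assert_allclose(
        groove_angle_series(spun).values, truth.groove_angle, atol=1e-9
    )
    np.testing.assert_allclose(tm_tilt_series(spun).values, truth.tm_tilt, atol=1e-9)


def test_cross_product_flip_is_an_involution(piecewise_run):
    traj, _ = piecewise_run
    phi = groove_angle_series(traj)
    flipped = groove_angle_series(traj, GrooveVectorDef(flip=True))
    np.testing.assert_allclose(flipped.values, 180.0 - phi.values, atol=1e-9)


def test_noisy_recovery_within_two_degrees(toy, slab):
    from groovedyn import AngleSchedule, make_rigid_body_trajectory

    schedule = AngleSchedule("piecewise", levels=[100.0, 40.0], switch_fractions=[0.6])
    traj, truth = make_rigid_body_trajectory(
        toy, slab, schedule, n_frames=300, seed=7, noise_sd=0.5
    )
    err = np.abs(groove_angle_series(traj).values - truth.groove_angle)
    assert err.mean() < 2.0


def test_frozen_axis_mode_uses_frame0_vector(piecewise_run):
    traj, truth = piecewise_run
    frozen = groove_angle_series(traj, frozen_axis=True)
    # the frame-0 groove vector never moves, so the series is constant
    np.testing.assert_allclose(frozen.values, truth.groove_angle[0], atol=1e-9)
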