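import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_rotation
from groovedyn import (
    AngleSchedule,
    LoopDefinition,
    SelectionSpec,
    make_rigid_body_trajectory,
    radius_of_gyration,
    residue_z_series,
    rg_series,
)
from groovedyn.errors import SelectionError
from test_groove_geometry import ca_model


def brute_force_rg(points: np.ndarray) -> float:
    """Pairwise oracle: Rg² = (1/2N²) Σ_i Σ_j |r_i − r_j|²."""
    n = len(points)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += np.sum((points[i] - points[j]) ** 2)
    return float(np.sqrt(total / (2 * n * n)))


def test_default_loop_spans_61_residues(toy):
    loop = LoopDefinition()
    assert loop.n_residues == 61
    assert len(toy.select(loop.selection)) == 61


def test_single_atom_rg_is_zero():
    model = ca_model(np.array([[1.0, 2.0, 3.0]]), start=21)
    assert radius_of_gyration(model, SelectionSpec(21, 21, "CA")) == 0.0


def test_two_points_rg_is_half_distance():
    model = ca_model(np.array([[0.0, 0.0, 0.0], [6.0, 0.0, 0.0]]), start=21)
    assert radius_of_gyration(model, SelectionSpec(21, 22, "CA")) == pytest.approx(3.0)


@pytest.mark.parametrize("n,a", [(5, 1.0), (61, 3.8), (10, 0.5)])
def test_collinear_beads_match_closed_form(n, a):
    points = np.column_stack([a * np.arange(n), np.zeros(n), np.zeros(n)])
    model = ca_model(points, start=21)
    rg = radius_of_gyration(model, SelectionSpec(21, 21 + n - 1, "CA"))
    assert rg**2 == pytest.approx(a**2 * (n**2 - 1) / 12, rel=1e-12)
    assert rg == pytest.approx(brute_force_rg(points), rel=1e-12)


def test_rg_matches_pairwise_oracle_on_random_point_sets():
    rng = np.random.default_rng(6)
    for _ in range(100):
        points = rng.standard_normal((int(rng.integers(2, 25)), 3)) * 4
        model = ca_model(points, start=21)
        sel = SelectionSpec(21, 21 + len(points) - 1, "CA")
        assert radius_of_gyration(model, sel) == pytest.approx(
            brute_force_rg(points), rel=1e-9
        )


@settings(deadline=None, max_examples=30, derandomize=True)
@given(seed=st.integers(0, 2**16), shift=st.floats(-50, 50))
def test_rg_invariant_under_rigid_motion(seed, shift):
    rng = np.random.default_rng(seed)
    points = rng.standard_normal((12, 3)) * 5
    model = ca_model(points, start=21)
    sel = SelectionSpec(21, 32, "CA")
    moved = model.transformed(random_rotation(rng), np.array([shift, -shift, shift]))
    assert radius_of_gyration(moved, sel) == pytest.approx(
        radius_of_gyration(model, sel), abs=1e-9
    )


def test_empty_selection_raises(toy):
    with pytest.raises(SelectionError):
        radius_of_gyration(toy, SelectionSpec(500, 600, "CA"))


def test_breathing_loop_schedule_recovered(toy, slab):
    targets = 9.0 + 3.0 * np.sin(np.linspace(0, 2 * np.pi, 40))
    traj, truth = make_rigid_body_trajectory(
        toy, slab, AngleSchedule("constant", levels=[95.0]),
        n_frames=40, loop_rg=targets, seed=2,
    )
    recovered = rg_series(traj)
    np.testing.assert_allclose(recovered.values, targets, atol=1e-6)
    assert recovered.values.min() == pytest.approx(targets.min(), abs=1e-6)
    assert recovered.values.max() == pytest.approx(targets.max(), abs=1e-6)


def test_rigid_trajectory_has_constant_rg(piecewise_run):
    traj, truth = piecewise_run
    values = rg_series(traj).values
    assert np.ptp(values) < 1e-9
    np.testing.assert_allclose(values, truth.loop_rg, atol=1e-9)


def test_condition_with_broader_prescribed_rg_recovers_broader_distribution(toy, slab):
    """Mirrors comparing a flexible-loop condition against a stiff one: the
    condition generated with larger Rg variance must yield the wider
    recovered distribution."""
    rng = np.random.default_rng(10)
    narrow = 9.0 + 0.3 * rng.standard_normal(60)
    broad = 9.0 + 1.5 * rng.standard_normal(60)
    sched = AngleSchedule("constant", levels=[95.0])
    widths = {}
    for name, targets in [("narrow", narrow), ("broad", broad)]:
        traj, _ = make_rigid_body_trajectory(
            toy, slab, sched, n_frames=60, loop_rg=targets, seed=3
        )
        widths[name] = rg_series(traj).values.std()
    assert widths["broad"] > widths["narrow"]


def test_scripted_residue_z_distributions(toy, slab):
    """One residue pinned at the phosphate plane, another in bulk solvent:
    the recovered z-distributions separate accordingly."""
    traj, _ = make_rigid_body_trajectory(
        toy, slab, AngleSchedule("constant", levels=[100.0]),
        n_frames=30, residue_z={21: 0.0, 70: 15.0}, seed=4,
    )
    z21 = residue_z_series(traj, 21).values
    z70 = residue_z_series(traj, 70).values
    np.testing.assert_allclose(z21, 0.0, atol=1e-9)
    np.testing.assert_allclose(z70, 15.0, atol=1e-9)


def test_missing_residue_z_raises(piecewise_run):
    traj, _ = piecewise_run
    with pytest.raises(SelectionError):
        residue_z_series(traj, 400)
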