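import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import random_rotation
from groovedyn import (
    ALPHA8,
    ConfigError,
    EmbeddingSpec,
    JoinSpec,
    MembraneFrame,
    SelectionSpec,
    align_helix_to_z,
    embed_in_membrane,
    helix_principal_axis,
    join_structures,
    make_anchored_toy,
    make_ideal_helix,
    superpose,
)
from groovedyn.errors import ConstraintError
from groovedyn.model_builder import embedding_report


def pairwise_distances(model):
    x = model.positions
    return np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)


def test_align_already_aligned_is_identity_up_to_noise():
    helix = make_ideal_helix(23, start_residue=209)
    aligned = align_helix_to_z(helix, ALPHA8)
    np.testing.assert_allclose(aligned.positions, helix.positions, atol=1e-9)


def test_align_helix_built_along_x():
    rot_to_x = Rotation.from_rotvec([0.0, np.pi / 2, 0.0]).as_matrix()
    helix = make_ideal_helix(23, start_residue=209, rotation=rot_to_x)
    aligned = align_helix_to_z(helix, ALPHA8)
    axis = helix_principal_axis(aligned, ALPHA8)
    assert np.degrees(np.arccos(min(axis[2], 1.0))) < 1e-6


def test_align_random_placement_recovers_reference():
    """Oracle: independent least-squares superposition onto a directly-built
    z-aligned helix gives RMSD ~ 0 after alignment."""
    rng = np.random.default_rng(12)
    reference = make_ideal_helix(23, start_residue=209)
    for _ in range(10):
        placed = reference.transformed(random_rotation(rng), rng.normal(0, 30, 3))
        aligned = align_helix_to_z(placed, ALPHA8)
        axis = helix_principal_axis(aligned, ALPHA8)
        assert np.degrees(np.arccos(np.clip(axis[2], -1, 1))) < 1e-6
        _, _, rmsd = superpose(aligned.positions, reference.positions)
        assert rmsd < 1e-6
        # rigid: pairwise distances preserved
        np.testing.assert_allclose(
            pairwise_distances(aligned), pairwise_distances(placed), atol=1e-6
        )


def split_head_tail(model, head_last=222, tail_first=209):
    head = model.subset(np.nonzero(model.residue_numbers <= head_last)[0])
    tail = model.subset(np.nonzero(model.residue_numbers >= tail_first)[0])
    return head, tail


def test_join_identity_overlap_restores_original(toy):
    head, tail = split_head_tail(toy)
    chimera, rmsd = join_structures(JoinSpec(head_model=head, tail_model=tail))
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert chimera.n_atoms == toy.n_atoms
    np.testing.assert_allclose(chimera.positions, toy.positions, atol=1e-9)
    # single chain, contiguous numbering from both sources
    assert set(chimera.chain_ids) == {"A"}


def test_join_recovers_rigidly_perturbed_head(toy):
    rng = np.random.default_rng(3)
    head, tail = split_head_tail(toy)
    rot = random_rotation(rng)
    perturbed = head.transformed(rot, rng.normal(0, 15, 3))
    chimera, rmsd = join_structures(JoinSpec(head_model=perturbed, tail_model=tail))
    assert rmsd < 1e-6
    np.testing.assert_allclose(chimera.positions, toy.positions, atol=1e-6)


def test_join_residue_ownership(toy):
    """Residues ≤ junction come from the head source, residues > junction
    from the tail."""
    head, tail = split_head_tail(toy)
    tail = tail.transformed(None, np.array([0.0, 0.0, 0.0]))
    chimera, _ = join_structures(JoinSpec(head_model=head, tail_model=tail))
    assert chimera.residue_numbers.min() == 1
    assert chimera.residue_numbers.max() == 231
    counts = {r: 1 for r in chimera.residue_numbers}
    assert len(counts) == len(chimera.residue_numbers)  # no duplicated residues


def test_join_junction_outside_head_raises(toy):
    head, tail = split_head_tail(toy)
    with pytest.raises(ConfigError):
        JoinSpec(head_model=head, tail_model=tail, junction_residue=300)


def test_join_mismatched_overlap_warns(toy):
    head, tail = split_head_tail(toy)
    jostled = head.copy()
    idx = jostled.select(SelectionSpec(207, 214, "CA"))
    rng = np.random.default_rng(0)
    jostled.positions[idx] += rng.normal(0, 4.0, (len(idx), 3))
    with pytest.warns(UserWarning, match="RMSD"):
        join_structures(JoinSpec(head_model=jostled, tail_model=tail))


def embedding_case(half_gap):
    # tall helix so the TM span covers the plane gap
    toy = make_anchored_toy()
    mem = MembraneFrame(np.array([0.0, 0.0, 1.0]), half_gap, -half_gap)
    return toy, mem


def test_embedding_satisfies_all_constraints():
    toy, mem = embedding_case(14.0)
    spec = EmbeddingSpec()
    embedded = embed_in_membrane(toy, mem, spec)
    report = embedding_report(embedded, mem, spec)
    assert 0.0 < report["anchor_depth"] <= spec.anchor_depth
    assert report["head_gap"] <= spec.max_head_gap
    assert report["tm_top_z"] >= mem.upper_plane_z
    assert report["tm_bottom_z"] <= mem.lower_plane_z
    # rigid z-translation only
    np.testing.assert_allclose(
        embedded.positions[:, :2], toy.positions[:, :2], atol=1e-12
    )


def test_embedding_closes_head_gap():
    toy, mem = embedding_case(14.0)
    lifted = toy.transformed(None, np.array([0.0, 0.0, 50.0]))  # head far above
    spec = EmbeddingSpec()
    before = embedding_report(lifted, mem, spec)["head_gap"]
    assert before > spec.max_head_gap
    embedded = embed_in_membrane(lifted, mem, spec)
    assert embedding_report(embedded, mem, spec)["head_gap"] <= spec.max_head_gap


def test_embedding_infeasible_plane_gap_names_constraint():
    toy, mem = embedding_case(40.0)  # gap far wider than the TM helix
    with pytest.raises(ConstraintError, match="span"):
        embed_in_membrane(toy, mem, EmbeddingSpec())


def test_superpose_is_exact_on_rigid_copies():
    rng = np.random.default_rng(8)
    x = rng.standard_normal((20, 3)) * 5
    rot = random_rotation(rng)
    t = rng.normal(0, 10, 3)
    r_fit, t_fit, rmsd = superpose(x @ rot.T + t, x)
    assert rmsd < 1e-6
    np.testing.assert_allclose(r_fit @ rot, np.eye(3), atol=1e-9)
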