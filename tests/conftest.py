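import numpy as np
import pytest

from groovedyn import (
    AngleSchedule,
    make_anchored_toy,
    make_membrane_slab,
    make_rigid_body_trajectory,
)


@pytest.fixture(scope="session")
def toy():
    return make_anchored_toy()


@pytest.fixture(scope="session")
def slab():
    return make_membrane_slab(seed=0)


@pytest.fixture(scope="session")
def piecewise_run(toy, slab):
    """500-frame rigid-body trajectory: groove at 100° for the first 60% of
    frames, then a sharp transition to 40°; TM tilt held at 15°."""
    schedule = AngleSchedule("piecewise", levels=[100.0, 40.0], switch_fractions=[0.6])
    traj, truth = make_rigid_body_trajectory(
        toy, slab, schedule, n_frames=500, dt_us=0.01, tm_tilt_deg=15.0, seed=11
    )
    return traj, truth


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
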