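import numpy as np
import pytest

from memsta.geometry import normal_to_orientation
from memsta.particles import ParticleSet


def make_set(
    positions,
    cc=None,
    matrices=None,
    tomo_id=None,
    object_id=None,
    shifts=None,
    voxel_size=1.0,
):
    """Build a ParticleSet from bare arrays with sensible defaults."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    if matrices is None:
        matrices = np.tile(np.eye(3), (n, 1, 1))
    return ParticleSet(
        tags=np.arange(1, n + 1),
        tomo_id=np.ones(n, int) if tomo_id is None else np.asarray(tomo_id),
        object_id=np.ones(n, int) if object_id is None else np.asarray(object_id),
        positions=positions,
        shifts=np.zeros((n, 3)) if shifts is None else np.asarray(shifts, dtype=float),
        matrices=np.asarray(matrices, dtype=float),
        cc=np.zeros(n) if cc is None else np.asarray(cc, dtype=float),
        voxel_size=voxel_size,
    )


def set_with_thetas(thetas_deg, cc, rng=None):
    """Particles whose membrane normals sit at the given latitude angles."""
    rng = rng or np.random.default_rng(0)
    thetas = np.deg2rad(np.asarray(thetas_deg, dtype=float))
    phis = rng.uniform(0, 2 * np.pi, size=len(thetas))
    mats = []
    for t, p in zip(thetas, phis):
        n = np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])
        mats.append(normal_to_orientation(n).matrix)
    positions = rng.uniform(0, 100, size=(len(thetas), 3))
    return make_set(positions, cc=cc, matrices=np.array(mats))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
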