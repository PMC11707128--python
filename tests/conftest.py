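import numpy as np
import pytest
import trimesh


@pytest.fixture
def unit_cube() -> trimesh.Trimesh:
    """Unit cube centred at the origin."""
    return trimesh.creation.box(extents=[1.0, 1.0, 1.0])


@pytest.fixture
def icosphere() -> trimesh.Trimesh:
    return trimesh.creation.icosphere(subdivisions=3, radius=10.0)


def make_ball_field(radius: float, grid_n: int):
    """Partial-volume (anti-aliased) voxelization of a centred ball.

    The field crosses 0.5 exactly where the distance to the centre equals the
    radius, so marching cubes at iso 0.5 reconstructs the sphere.
    """
    g = np.indices((grid_n,) * 3).astype(np.float64) - (grid_n - 1) / 2
    dist = np.sqrt((g ** 2).sum(axis=0))
    return np.clip(0.5 + (radius - dist), 0.0, 1.0).astype(np.float32)
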