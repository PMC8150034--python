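import numpy as np
import pytest

from osteofabric.phantom import PhantomSpec, make_long_bone
from osteofabric.volume_io import VoxelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_tube_spec(model=("none",), seed=0, **kw):
    """A compact tube phantom used across test modules (~70x70x104 voxels)."""
    base = dict(
        length=2500.0,
        outer_radius_profile=("constant", 800.0),
        cortical_thickness=200.0,
        trabecular_model=model,
        spacing=25.0,
        seed=seed,
    )
    base.update(kw)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def tube_with_rods():
    """Noise-free tube filled with long-axis-aligned rods + ground truth."""
    spec = small_tube_spec(model=("aligned_rods", 0.0, 7.5, 75.0, 0.3), seed=3)
    return make_long_bone(spec)


@pytest.fixture(scope="session")
def hollow_tube():
    spec = small_tube_spec(model=("none",), seed=0)
    return make_long_bone(spec)


@pytest.fixture
def constant_volume():
    return VoxelVolume(np.full((12, 12, 12), 7.0, dtype=np.float32), 20.0)


def solid_cylinder_mask(shape=(40, 40, 60), radius=15.0, axis=2):
    c = (np.array(shape) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    in_plane = [g - c[i] for i, g in enumerate(grids) if i != axis]
    return (in_plane[0] ** 2 + in_plane[1] ** 2) <= radius**2
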