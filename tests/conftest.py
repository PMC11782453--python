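import numpy as np
import pytest

from ablamarg import AnnotatedVolume


def make_vol(grid, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> AnnotatedVolume:
    return AnnotatedVolume(grid=np.asarray(grid, bool), spacing=spacing, origin=origin)


def random_blob(rng, shape, n_seeds=3, radius_range=(2.0, 6.0), spacing=(1.0, 1.0, 1.0)):
    """Union of random spheres voxelized on the grid — a generic test mask."""
    spacing = np.asarray(spacing, float)
    idx = np.indices(shape).reshape(3, -1).T * spacing
    grid = np.zeros(int(np.prod(shape)), dtype=bool)
    extent = spacing * (np.asarray(shape) - 1)
    for _ in range(n_seeds):
        center = rng.uniform(0.2, 0.8, 3) * extent
        r = rng.uniform(*radius_range)
        grid |= np.linalg.norm(idx - center, axis=1) <= r
    return grid.reshape(shape)


@pytest.fixture
def rng():
    return np.random.default_rng(20240802)
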