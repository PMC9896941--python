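import numpy as np
import pytest

from polqc import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_scene_params():
    """Fast-to-render scene: one cycle, two clusters, coarse volume."""
    return synthetic.SceneParams(
        volume_shape=(22, 80, 80),
        voxel_size=(150.0, 100.0, 100.0),
        n_clusters=2,
        cluster_axes=(800.0, 550.0, 550.0),
        n_frames=16,
        frame_interval=2.0,
        cycle_period=30.0,
        lag_ser2p=5.0,
        lag_shape=10.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_scene(small_scene_params):
    return synthetic.render_scene(small_scene_params)


def make_ellipsoid_mask(shape, center, semi_axes, voxel_size=(1.0, 1.0, 1.0)):
    """Analytic ellipsoid voxelization on voxel centers (z, y, x order)."""
    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * v for n, v in zip(shape, voxel_size)],
        indexing="ij",
    )
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0
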