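import numpy as np
import pytest

from loctrans import synthetic as syn
from loctrans.config import RunConfig


@pytest.fixture(scope="session")
def small_embryo():
    """8-cell embryo in a 32x96x96 grid; shared, treat as read-only."""
    geom = syn.EmbryoGeometry(
        volume_shape=(32, 96, 96), n_cells=8, seed=11
    )
    membrane, labels, mask = syn.generate_embryo(geom)
    return geom, membrane, labels, mask


@pytest.fixture(scope="session")
def seg_embryo():
    """16-cell embryo at the resolution used for segmentation checks."""
    geom = syn.EmbryoGeometry(
        volume_shape=(64, 128, 128), n_cells=16, seed=5
    )
    membrane, labels, mask = syn.generate_embryo(geom)
    return geom, membrane, labels, mask


@pytest.fixture()
def cfg():
    return RunConfig()


def brute_force_distance_map(boundary: np.ndarray, voxel_size) -> np.ndarray:
    """O(N^2) nearest-boundary-voxel-centre search; the distance oracle."""
    vs = np.asarray(voxel_size, dtype=float)
    pts = np.argwhere(boundary) * vs
    shape = boundary.shape
    grid = (
        np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), -1)
        .reshape(-1, len(shape))
        * vs
    )
    d = np.sqrt(((grid[:, None, :] - pts[None, :, :]) ** 2).sum(-1)).min(1)
    return d.reshape(shape)
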