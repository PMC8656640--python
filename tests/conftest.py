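import numpy as np
import pytest

from spherolec import BinaryMask, ImageStack, PhantomConfig


@pytest.fixture
def unit_voxel():
    return (1.0, 1.0, 1.0)


@pytest.fixture
def small_phantom_config():
    """A reduced-size phantom for fast unit tests (not the study defaults)."""
    return PhantomConfig(
        grid_shape=(24, 96, 96),
        n_spheroids=2,
        network_node_count=5,
        seed=7,
    )


def make_stack(values, voxel_size=(1.0, 1.0, 1.0), channel="other", meta=None):
    return ImageStack(np.asarray(values), voxel_size, channel=channel, meta=meta or {})


def make_ball_mask(shape, center, radius, voxel_size=(1.0, 1.0, 1.0), channel="other"):
    """Rasterized ball: voxel centres (i+0.5)*v within radius of center (µm)."""
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    dist2 = sum(((g + 0.5) * v - c) ** 2 for g, v, c in zip(grids, voxel_size, center))
    return BinaryMask(dist2 <= radius**2, voxel_size, channel)


@pytest.fixture
def toy_overlap_masks():
    """Hand-countable fixture: LEC = 1000 unit voxels, one 100-voxel
    spheroid with exactly 80 voxels inside the LEC mask."""
    shape = (10, 20, 20)
    lec = np.zeros(shape, dtype=bool)
    lec[0:10, 0:10, 0:10] = True  # 1000 voxels
    assert lec.sum() == 1000
    tnbc = np.zeros(shape, dtype=bool)
    tnbc[2:6, 6:11, 5:10] = True  # 4 x 5 x 5 = 100 voxels
    assert tnbc.sum() == 100
    # inside slab: z 2:6 (4) * y 6:10 (4) * x 5:10 (5) = 80 voxels
    assert (tnbc & lec).sum() == 80
    return (
        BinaryMask(tnbc, (1.0, 1.0, 1.0), "TNBC"),
        BinaryMask(lec, (1.0, 1.0, 1.0), "LEC"),
    )
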