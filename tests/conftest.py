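import numpy as np
import pytest

from xfiquant.voxel_model import CTVolume, build_material_map, default_hu_table


@pytest.fixture(scope="session")
def hu_table():
    return default_hu_table()


@pytest.fixture()
def soft_cube():
    """10 mm uniform soft-tissue cube, 0.5 mm voxels, centered at the origin."""
    n = 20
    ct = CTVolume(np.zeros((n, n, n), dtype=np.float32), (0.5, 0.5, 0.5),
                  tuple(-(n - 1) / 2 * 0.5 for _ in range(3)))
    return build_material_map(ct)


@pytest.fixture()
def blocks_volume():
    """Random-blocks phantom: random material labels on a coarse 3-D grid."""
    rng = np.random.default_rng(7)
    table = default_hu_table()
    mids = table.midpoints()
    coarse = rng.integers(0, len(mids), size=(6, 5, 4))
    hu = np.repeat(np.repeat(np.repeat(mids[coarse], 5, 0), 5, 1), 5, 2)
    ct = CTVolume(hu.astype(np.float32), (0.4, 0.4, 0.4),
                  tuple(-(n - 1) / 2 * 0.4 for n in hu.shape))
    return build_material_map(ct)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
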