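import numpy as np
import pytest

from triconj.volume_io import AcquisitionGrid, Mask, Volume


@pytest.fixture
def small_grid() -> AcquisitionGrid:
    return AcquisitionGrid.centered((16, 16, 10), (3.4375, 3.4375, 4.0), 2.0)


@pytest.fixture
def tiny_grid() -> AcquisitionGrid:
    return AcquisitionGrid.centered((6, 6, 4), (3.0, 3.0, 3.0), 2.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_volume(values, grid) -> Volume:
    return Volume(values=np.asarray(values, dtype=float), grid=grid)


def make_mask(member, grid) -> Mask:
    return Mask(membership=np.asarray(member, dtype=bool), grid=grid)
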