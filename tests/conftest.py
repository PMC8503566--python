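import numpy as np
import pytest

from mvba import BinaryMask, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_config():
    """Desk-scale cohort config used by fast structural tests."""
    return SyntheticConfig(
        shape=(16, 16, 16), voxel_size_mm=(2.0, 2.0, 2.0), n_controls=4,
        cerebellar_region=((4, 10), (4, 10), (2, 8)), seed=11,
    )


@pytest.fixture
def full_mask():
    def _make(shape):
        return BinaryMask(np.ones(shape, dtype=bool))
    return _make
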