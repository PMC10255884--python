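import numpy as np
import pytest

from marblingnet.synthetic import SyntheticParams, generate_image


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sample():
    """One deterministic 100x200 synthetic image/mask pair."""
    params = SyntheticParams.for_size(100, 200)
    return generate_image(params, np.random.default_rng(7))


@pytest.fixture(scope="session")
def checker_mask():
    """A 16x16 checkerboard-ish mask with a few foreground blobs."""
    mask = np.zeros((16, 16), dtype=np.uint8)
    mask[2:5, 2:5] = 1
    mask[10:12, 8:14] = 1
    mask[7, 7] = 1
    return mask
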