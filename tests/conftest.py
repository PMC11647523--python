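import numpy as np
import pytest

from gstrpca import make_irregular


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_tensor(rng):
    """K=2 irregular tensor with row_dims [4, 9], M=6."""
    return make_irregular([rng.normal(size=(4, 6)), rng.normal(size=(9, 6))])


@pytest.fixture
def three_slice_tensor(rng):
    return make_irregular(
        [rng.normal(size=(3, 5)), rng.normal(size=(7, 5)), rng.normal(size=(2, 5))]
    )
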