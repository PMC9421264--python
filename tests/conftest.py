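import numpy as np
import pytest

from mirtvae.model import ItemParameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params(rng):
    """A small random 4PL item set (J=4, K=2)."""
    return ItemParameters(
        loadings=rng.standard_normal((4, 2)),
        intercepts=rng.standard_normal(4),
        guessing_raw=rng.standard_normal(4),
        upper_raw=rng.standard_normal(4),
        model="4pl",
    )


@pytest.fixture
def tiny_batch(rng):
    """Responses and a mask with a few missing cells (B=3, J=4)."""
    y = (rng.random((3, 4)) < 0.5).astype(float)
    mask = np.ones((3, 4))
    mask[0, 1] = 0.0
    mask[2, 3] = 0.0
    return y * mask, mask
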