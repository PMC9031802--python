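import sys
from pathlib import Path

import numpy as np
import pytest
from scipy import ndimage

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def smooth_texture(rng, shape=(64, 64), sigma=2.0, lo=20.0, hi=220.0):
    """Band-limited random texture suitable for small-motion optical flow."""
    tex = ndimage.gaussian_filter(rng.uniform(0, 1, shape), sigma, mode="wrap")
    tex = (tex - tex.min()) / (tex.max() - tex.min())
    return lo + (hi - lo) * tex


@pytest.fixture
def texture(rng):
    return smooth_texture(rng)
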