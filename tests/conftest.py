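import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `reference` importable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_int_image(rng):
    """16x16 random 8-bit-style integer image (as float)."""
    return rng.integers(0, 256, size=(16, 16)).astype(np.float64)


@pytest.fixture
def random_float_image(rng):
    """32x32 continuous-valued image in [0, 255] (tie-free a.s.)."""
    return rng.random((32, 32)) * 255.0
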