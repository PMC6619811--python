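import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from planktonseg.image_io import GrayFrame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_frame(rng):
    """A 64x64 8-bit frame of uniform random intensities."""
    return GrayFrame(rng.integers(0, 256, (64, 64)).astype(np.uint8), 8, "rand64")


def make_frame(pixels, bit_depth=8, frame_id="f"):
    return GrayFrame(np.asarray(pixels), bit_depth=bit_depth, frame_id=frame_id)


@pytest.fixture
def frame_factory():
    return make_frame
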