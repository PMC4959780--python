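import numpy as np
import pytest

from aostain.camera_io import CameraConfig, ChannelStack
from aostain.photophysics import default_response


@pytest.fixture(scope="session")
def camera() -> CameraConfig:
    return CameraConfig()


@pytest.fixture(scope="session")
def response():
    return default_response()


def make_stack(red, green=None, blue=None, provenance=()):
    """Build a ChannelStack from arrays, defaulting green/blue to red."""
    red = np.asarray(red, dtype=float)
    green = red.copy() if green is None else np.asarray(green, dtype=float)
    blue = red.copy() if blue is None else np.asarray(blue, dtype=float)
    return ChannelStack(red=red, green=green, blue=blue,
                        provenance=tuple(provenance))


@pytest.fixture
def rng():
    return np.random.default_rng(20160725)
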