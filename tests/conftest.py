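import numpy as np
import pytest

from eeslab.paddle_geometry import build_layout, hd64_spec, normalize_coords
from eeslab.synthetic_data import default_ground_truth


@pytest.fixture(scope="session")
def hd64_layout():
    return normalize_coords(build_layout(hd64_spec()))


@pytest.fixture(scope="session")
def ground_truth():
    return default_ground_truth()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
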