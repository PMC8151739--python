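import numpy as np
import pytest

from pillowfit import GeneratorConfig, PressureMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gen_config():
    return GeneratorConfig(seed=7)


@pytest.fixture
def const2():
    """Constant 2 kPa matrix."""
    return PressureMatrix(np.full((4, 4), 2.0), pitch_cm=1.0)


@pytest.fixture
def quad():
    """The 2x2 matrix [[1,2],[3,4]] kPa at unit pitch."""
    return PressureMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]), pitch_cm=1.0)


def random_matrix(rng, rows=6, cols=6, scale=5.0, pitch=1.1):
    vals = rng.random((rows, cols)) * scale
    return PressureMatrix(vals, pitch_cm=pitch, contact_threshold_kpa=0.1)
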