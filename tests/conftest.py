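import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "seedlingscreen",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("seedlingscreen")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


# Published validation confusion matrices (rows = predicted, cols = true,
# class order healthy/unhealthy/none) used as arithmetic fixtures.
CM_NETWORK = np.array([[439, 11, 0], [12, 138, 0], [0, 0, 300]])
CM_PHYSICAL = np.array([[399, 41, 0], [55, 105, 0], [0, 0, 300]])


@pytest.fixture
def cm_network() -> np.ndarray:
    return CM_NETWORK.copy()


@pytest.fixture
def cm_physical() -> np.ndarray:
    return CM_PHYSICAL.copy()
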