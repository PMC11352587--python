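import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def checkerboard4():
    """4x4 checkerboard starting with white in the top-left corner."""
    base = np.indices((4, 4)).sum(axis=0) % 2
    return (1 - base).astype(np.uint8)


@pytest.fixture
def five_pattern_dist():
    """The worked five-pattern distribution used across selection tests."""
    return {0: 0.5, 1: 0.2, 2: 0.15, 3: 0.1, 4: 0.05}
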