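import numpy as np
import pytest

from spikedisc import NetworkConfig, generate_flag_patterns


@pytest.fixture
def cfg():
    """Full-size configuration with default parameters."""
    return NetworkConfig()


@pytest.fixture
def desk_cfg():
    """Scaled-down configuration used for simulation tests."""
    return NetworkConfig.desk()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def patterns(rng):
    return generate_flag_patterns(8, 15, rng)
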