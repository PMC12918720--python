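import numpy as np
import pytest

from stedcount import SimulationConfig


@pytest.fixture
def quiet_config() -> SimulationConfig:
    """Deterministic imaging: no noise, no brightness variation, full occupancy."""
    return SimulationConfig(seed=7, noise="none", brightness_cv=0.0,
                            occupancy_p=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
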