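import numpy as np
import pytest

from spinetrack import SimulationParams, simulate_stack

SMALL_PARAMS = SimulationParams(image_size=256, n_slices=12, n_spines=8, seed=3)


@pytest.fixture(scope="session")
def small_stack():
    """One small synthetic stack with its exact ground truth, shared read-only."""
    return simulate_stack(SMALL_PARAMS)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
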