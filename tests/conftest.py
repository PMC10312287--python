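import numpy as np
import pytest

from commchange import SimulationConfig, run_baseline


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_baseline():
    """A modest fixed-parameter baseline shared by fast experiment tests."""
    return run_baseline(SimulationConfig(seed=11, n_bold_steps=500), n_runs=40)
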