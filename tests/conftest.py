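import numpy as np
import pytest

from maternet.simulate import SimConfig, default_config, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """3 dams per group, full PPD range: fast but structurally complete."""
    return simulate_dataset(SimConfig(n_dams_per_group=3, seed=7))


@pytest.fixture(scope="session")
def default_dataset():
    """The full study design: 9 dams per group, PPD 2-9, 3 periods/day."""
    return simulate_dataset(default_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
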