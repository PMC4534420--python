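import numpy as np
import pytest

from aslpower import (KineticParams, NoiseConfig, PhantomConfig,
                      get_protocol, sample_tissue_map, simulate_series)


@pytest.fixture(scope="session")
def exp3():
    return get_protocol("exp3")


@pytest.fixture(scope="session")
def small_phantom():
    """Compact phantom reused across tests (deterministic, seed 7)."""
    return sample_tissue_map(config=PhantomConfig(shape=(20, 20, 8)), seed=7)


@pytest.fixture(scope="session")
def small_subject(exp3, small_phantom):
    """One simulated subject on the compact phantom (default noise)."""
    return simulate_series(small_phantom, exp3, KineticParams(),
                           NoiseConfig(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
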