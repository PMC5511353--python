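import numpy as np
import pytest

from ccsquant import LocalizationTable, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table(rng):
    n = 50
    return LocalizationTable.from_arrays(
        rng.uniform(0, 2000, n),
        rng.uniform(0, 2000, n),
        frame=rng.integers(0, 100, n),
        intensity=rng.uniform(100, 1000, n),
        uncertainty_nm=rng.uniform(5, 25, n),
        channel=rng.integers(0, 2, n),
    )


@pytest.fixture
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture
def quiet_movie_config():
    """Zero-noise movie settings for closed-form oracles."""
    return SimulationConfig(
        seed=1,
        n_frames=30,
        lifetime_mode="full",
        bleach_tau_s=np.inf,
        poisson_noise=False,
        read_noise_sd=0.0,
        movie_step_sd_nm=0.0,
    )
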