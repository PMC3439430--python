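import numpy as np
import pytest

from glycosync import PopulationConfig, simulate_population


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def short_config():
    """Small, fast population: 12 cells, 600 s, everything else default."""
    return PopulationConfig(n_cells=12, duration_s=600.0, seed=7)


@pytest.fixture(scope="session")
def short_population(short_config):
    return simulate_population(short_config, with_positions=True)


@pytest.fixture(scope="session")
def synchronised_population():
    """Strongly coupled, narrow period spread: the coherent reference case."""
    cfg = PopulationConfig(n_cells=50, coupling_scale=3.0, period_sd_s=3.0,
                           density_pct=0.3, seed=11)
    return cfg, simulate_population(cfg)


@pytest.fixture(scope="session")
def desynchronised_population():
    """Uncoupled, broad period spread: the incoherent reference case."""
    cfg = PopulationConfig(n_cells=30, coupling_scale=0.0, period_mean_s=40.0,
                           period_sd_s=8.0, seed=13)
    return cfg, simulate_population(cfg)
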