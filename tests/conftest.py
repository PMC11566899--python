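import numpy as np
import pytest

from methyloscope.simulate import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_chroms=2,
        chrom_length=40_000,
        n_cgis=3,
        cgi_length_range=(500, 900),
        n_samples_per_breed={"akita": 2, "beagle": 2},
        mean_depth=40.0,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return simulate_genome(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
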