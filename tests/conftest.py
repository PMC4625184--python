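import numpy as np
import pytest

from piggytools.reporter import default_reporter
from piggytools.simulate import SimulationConfig, _sample_sequence, make_genome


def random_reporter(seed: int = 101, cargo_len: int = 600, variant: str = "intact"):
    rng = np.random.default_rng(seed)
    return default_reporter(_sample_sequence(rng, cargo_len, 0.5), variant=variant)


@pytest.fixture(scope="session")
def reporter():
    return random_reporter()


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        genome_length=200_000,
        contig_count=2,
        n_events=20,
        seed=3,
        duplicate_fraction=0.0,
        adapter_dimer_fraction=0.0,
        substitution_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return make_genome(small_config)
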