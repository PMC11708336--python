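import numpy as np
import pytest

from spacerscreen.genome import GenomeAnnotation, OperonRegion
from spacerscreen.simulate import SimulationConfig, simulate_genome


def random_sequence(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


@pytest.fixture(scope="session")
def phage_genome() -> GenomeAnnotation:
    """Full-scale synthetic phage: 40 kb, plus-strand early operon [1000,15000)
    firing at 5 min and late operon [15000,40000) firing at 15 min."""
    return simulate_genome(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_genome() -> GenomeAnnotation:
    """2 kb genome with the same proportional operon layout, for fast tests."""
    return GenomeAnnotation(
        name="mini_phage",
        sequence=random_sequence(2000, seed=7),
        operons=[
            OperonRegion(start=50, end=750, strand="+", activation_time=5.0, name="PE"),
            OperonRegion(start=750, end=2000, strand="+", activation_time=15.0, name="PL"),
        ],
    )
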