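import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("stable", derandomize=True)
settings.load_profile("stable")

sys.path.insert(0, str(Path(__file__).parent))  # make the oracle importable

from pcnv import SequenceRecord, SimulationConfig, make_clusters


@pytest.fixture
def worked_example() -> SequenceRecord:
    """The 9-nt hand-calculable sequence used throughout the docs."""
    return SequenceRecord("ex", "ACTGGCAAT")


@pytest.fixture(scope="session")
def default_clusters():
    """The standard synthetic genotyping dataset: 4 clusters of 10
    descendants, 5 kb genomes, 1% per-site substitution rate."""
    return make_clusters(SimulationConfig(n_clusters=4, per_cluster=10,
                                          length=5000, sub_rate=0.01, seed=42))


def random_dna(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))
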