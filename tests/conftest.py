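import numpy as np
import pytest

from seqrate.io_formats import ContactProbabilityMap
from seqrate.synthetic_data import SyntheticConfig, generate_benchmark


def random_symmetric_map(L: int, density: float, rng: np.random.Generator) -> ContactProbabilityMap:
    """Dense random probability map with the given fill density (all separations)."""
    probs = np.zeros((L, L))
    iu, ju = np.triu_indices(L, k=1)
    hit = rng.random(iu.shape) < density
    vals = np.where(hit, rng.random(iu.shape), 0.0)
    probs[iu, ju] = vals
    probs[ju, iu] = vals
    return ContactProbabilityMap(n=L, probs=probs)


@pytest.fixture(scope="session")
def small_benchmark():
    """16-protein synthetic benchmark with structures, shared across tests."""
    return generate_benchmark(SyntheticConfig(n_proteins=16, seed=3))


@pytest.fixture(scope="session")
def default_benchmark():
    """The default 80-protein benchmark (noise_sd = 0.3, seed 0)."""
    return generate_benchmark(SyntheticConfig(seed=0))
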