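import numpy as np
import pytest
from hypothesis import settings

from priorpc import BenchmarkSpec, make_benchmark

settings.register_profile("reproducible", derandomize=True, max_examples=50)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def small_benchmark():
    """20-gene benchmark used by several integration tests."""
    spec = BenchmarkSpec(n_nodes=20, n_edges=25, n_samples=120, seed=101)
    return make_benchmark(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
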