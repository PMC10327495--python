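import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from panblocks.merge import build_pangraph
from panblocks.simulate import (SimParams, mutation_rate_for_divergence,
                                simulate_population)

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_population():
    """10 circular 20 kb genomes at ~1 % average pairwise divergence."""
    mu = mutation_rate_for_divergence(0.01, 10, 50)
    params = SimParams(n=10, length=20_000, generations=50, mu=mu, seed=11)
    return simulate_population(params)


@pytest.fixture(scope="session")
def small_graph(small_population):
    genomes, _ = small_population
    return build_pangraph(genomes)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
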