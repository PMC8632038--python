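import numpy as np
import pytest

from wjsdm import (
    PriorKnowledge,
    SimulationConfig,
    compute_de_weights,
    copathway_matrix,
    estimate_covariances,
    simulate_scenario,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scenario():
    """One seeded synthetic scenario, small enough for per-test reuse."""
    config = SimulationConfig(p=30, K=2, n=60, missing_rate=0.3, prior_rate=0.5, seed=7)
    truth, data, G = simulate_scenario(config)
    return config, truth, data, G


@pytest.fixture(scope="session")
def small_fit_inputs(small_scenario):
    config, truth, data, G = small_scenario
    cov = estimate_covariances(data)
    de = compute_de_weights(data)
    F = copathway_matrix(
        {f"pw{i}": [truth.gene_ids[g] for g in pw] for i, pw in enumerate(truth.pathways)},
        truth.gene_ids,
    )
    prior = PriorKnowledge(G, F)
    return cov, de, prior, truth
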