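import pytest
from hypothesis import settings

from rvistools import io as rio
from rvistools import rvis_core, synthetic_data

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


def score_simulation(sim):
    return rvis_core.compute_rvis(
        rio.records_from_frame(sim.variants),
        sim.exons,
        sim.coverage_profile(),
        rho=sim.config.rho,
    )


@pytest.fixture(scope="session")
def small_sim():
    """300-gene synthetic exome with 10% intolerant genes."""
    cfg = synthetic_data.SimulationConfig(n_genes=300, seed=11)
    return synthetic_data.simulate_exome(cfg)


@pytest.fixture(scope="session")
def small_scores(small_sim):
    return score_simulation(small_sim)


@pytest.fixture(scope="session")
def default_sim():
    """The generator's stated default world: 2000 genes, 10% intolerant,
    suppression 0.2, seed 1."""
    return synthetic_data.simulate_exome(synthetic_data.SimulationConfig())


@pytest.fixture(scope="session")
def default_scores(default_sim):
    return score_simulation(default_sim)
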