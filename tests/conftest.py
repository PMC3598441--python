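import numpy as np
import pytest

from wccox import SimulationConfig, generate_population, sample_case_control
from wccox.evaluation import replication_rng, study_cox_arrays
from wccox.weights import CohortPiFunction


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_population():
    """A modest source population with ~10% events, reused across tests."""
    cfg = SimulationConfig(population_size=400, scenario="A", model=1,
                           target_event_rate=0.10, master_seed=7)
    return cfg, generate_population(cfg, replication_rng(7, 0))


@pytest.fixture(scope="session")
def small_study(small_population):
    """(config, population, study, pi, CoxArrays) for one 1:2 sampled study."""
    cfg, pop = small_population
    rng = replication_rng(7, 1)
    study = sample_case_control(pop, 2, rng)
    pi = CohortPiFunction(pop.exit_age, pop.event)
    d = study_cox_arrays(study, pop, pi, cfg.model)
    return cfg, pop, study, pi, d
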