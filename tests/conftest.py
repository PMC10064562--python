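import pytest

from pahpheno import (SimulationConfig, build_network, default_pah_exon_map,
                      find_hub_nodes, generate_cohort, generate_worked_fixture)


@pytest.fixture(scope="session")
def xmap():
    return default_pah_exon_map()


@pytest.fixture(scope="session")
def worked_db():
    return generate_worked_fixture()


@pytest.fixture(scope="session")
def worked_net(worked_db):
    return build_network(worked_db)


@pytest.fixture(scope="session")
def worked_hubs(worked_net):
    return find_hub_nodes(worked_net)


@pytest.fixture(scope="session")
def small_cohort():
    """A quick synthetic cohort with clean severity signal (n=400)."""
    cfg = SimulationConfig(n_patients=400, n_mutations=80,
                           phe_noise_sigma=0.1, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def signal_cohort():
    """The strong-signal cohort used for recovery checks
    (1200 patients, 200 mutations, lognormal sigma 0.1)."""
    cfg = SimulationConfig(n_patients=1200, n_mutations=200,
                           phe_noise_sigma=0.1, seed=1)
    return generate_cohort(cfg)
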