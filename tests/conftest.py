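import pytest

import fiscope as fs


@pytest.fixture(scope="session")
def sim_config():
    return fs.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def cohort(sim_config):
    """One simulated cohort shared across tests (read-only)."""
    raw, truth = fs.simulate_counts(sim_config)
    meta = fs.simulate_metadata(sim_config)
    return raw, truth, meta


@pytest.fixture(scope="session")
def normalized(cohort):
    raw, truth, meta = cohort
    return fs.normalize_lanes(raw)


@pytest.fixture(scope="session")
def de_result(normalized, cohort):
    _, _, meta = cohort
    return fs.differential_expression(normalized, meta.groups)
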