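import pytest

from forestbenefit import list_fixtures, load_scenario, run_simulation


@pytest.fixture(scope="session")
def bau_sim():
    return run_simulation(load_scenario("bau"))


@pytest.fixture(scope="session")
def all_sims():
    """One simulation per shipped scenario fixture, keyed by name."""
    return {name: run_simulation(load_scenario(name)) for name in list_fixtures()}
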