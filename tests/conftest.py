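import pytest

from onecarbon import (
    RegulationSwitches,
    male_parameters,
    run_to_steady_state,
)


@pytest.fixture(scope="session")
def params():
    return male_parameters()


@pytest.fixture(scope="session")
def switches():
    return RegulationSwitches()


@pytest.fixture(scope="session")
def male_ss(params, switches):
    """Converged male baseline steady state (shared across tests)."""
    res = run_to_steady_state(params, switches)
    assert res.converged
    return res
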