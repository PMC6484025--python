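import pytest

from miread import ScenarioSpec, generate
from miread.fixtures import SCENARIOS


@pytest.fixture(params=SCENARIOS)
def scenario_dataset(request):
    """One generated dataset per scenario shape."""
    return generate(ScenarioSpec(scenario=request.param, seed=7))


@pytest.fixture
def long_trap():
    return generate(ScenarioSpec(scenario="long_trap", seed=1, n_events=10,
                                 n_taxa=3))
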