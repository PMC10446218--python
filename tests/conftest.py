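import pytest

import markovcea as mc
from markovcea.sensitivity import ModelBundle


@pytest.fixture(scope="session")
def whole_group():
    return mc.reference_scenario("whole_group")


@pytest.fixture(scope="session")
def asian_subgroup():
    return mc.reference_scenario("asian_subgroup")


@pytest.fixture(scope="session")
def whole_group_bundle(whole_group):
    strategies, settings = whole_group
    return ModelBundle(strategies=tuple(strategies), settings=settings)


@pytest.fixture(scope="session")
def whole_group_results(whole_group):
    strategies, settings = whole_group
    return tuple(mc.run_strategy(s, settings) for s in strategies), settings
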