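import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helper

from thermoflux.synthetic_data import FixtureSpec, make_network_fixture


@pytest.fixture(scope="session")
def futile_cycle():
    return make_network_fixture(FixtureSpec(kind="futile_cycle", seed=1))


@pytest.fixture(scope="session")
def mini_core():
    return make_network_fixture(FixtureSpec(kind="mini_core", seed=1))


@pytest.fixture(scope="session")
def unknown_met():
    return make_network_fixture(FixtureSpec(kind="unknown_metabolite", seed=1))


@pytest.fixture(scope="session")
def chain():
    return make_network_fixture(FixtureSpec(kind="linear_chain", seed=7, n_reactions=5))
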