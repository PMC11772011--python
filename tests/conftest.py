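import logging

import pytest

from graftcea import (
    InductionCEA,
    default_config,
    packaged_cost_table,
    packaged_event_table,
)

logging.getLogger("graftcea").setLevel(logging.ERROR)
logging.getLogger("graftcea.inputs").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def events():
    return packaged_event_table()


@pytest.fixture(scope="session")
def costs(config):
    return packaged_cost_table(config)


@pytest.fixture(scope="session")
def model(events, costs, config):
    return InductionCEA(events, costs, config)
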