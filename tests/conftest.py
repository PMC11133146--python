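import numpy as np
import pytest

from habitsim.agents import AgentParams, simulate_participant
from habitsim.task_engine import TaskConfig, schedule_for_group


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def short_schedule():
    return schedule_for_group("short")


@pytest.fixture(scope="session")
def extensive_schedule():
    return schedule_for_group("extensive")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_log(config, short_schedule):
    """One deterministic synthetic participant in the short group."""
    return simulate_participant(AgentParams(), short_schedule, config, seed=7)


@pytest.fixture(scope="session")
def extensive_log(config, extensive_schedule):
    return simulate_participant(AgentParams(), extensive_schedule, config,
                                seed=11)
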