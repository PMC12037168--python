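import numpy as np
import pytest
from hypothesis import settings

from pushpull import agents, task_engine, value_models

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def q_agent_series():
    """One 5,000-trial bandit series from a known Q agent (alpha .5, beta 3)."""
    agent = agents.QAgent(agents.QAgentParams(alpha=0.5, beta=3.0))
    log = task_engine.run_bandit_session(
        agent, task_engine.ValueTaskConfig(), 5000, np.random.default_rng(77)
    )
    return value_models.series_from_session(log)


@pytest.fixture(scope="session")
def traced_bandit_session():
    """A 120-trial bandit session with synthetic joystick traces."""
    agent = agents.QAgent(agents.QAgentParams(alpha=0.5, beta=3.0))
    return task_engine.run_bandit_session(
        agent,
        task_engine.ValueTaskConfig(),
        120,
        np.random.default_rng(99),
        trace_policy=task_engine.TracePolicy(),
        p_omit=0.05,
        p_premature=0.02,
    )
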