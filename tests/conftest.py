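import numpy as np
import pytest

from flanksense import simulate


@pytest.fixture(scope="session")
def default_session():
    """A 60-minute simulated session with the default bout mixture."""
    schedule = simulate.default_schedule(3600.0, seed=11)
    trace, intervals = simulate.simulate_session(schedule)
    return schedule, trace, intervals


@pytest.fixture
def rng():
    return np.random.default_rng(42)
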