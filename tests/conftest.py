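import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pigscreen.core import EventLog, EventRecord, SessionContext, SimulatedClock

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ctx():
    """A fresh session context on a simulated clock."""
    return SessionContext(subject_id="pigA", session_id=1, task="ddt", clock=SimulatedClock())


def make_ctx(task="ddt", subject_id="pigA", session_id=1):
    return SessionContext(
        subject_id=subject_id, session_id=session_id, task=task, clock=SimulatedClock()
    )


def make_event(t=0.0, event_type="manual_note", **kw):
    defaults = dict(
        subject_id="pigA",
        session_id=1,
        task="ddt",
        phase="test",
        event_type=event_type,
        timestamp=t,
    )
    defaults.update(kw)
    return EventRecord(**defaults)
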