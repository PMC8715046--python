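import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pupilkit import EventLog, PipelineConfig

# the `config` fixture is an immutable dataclass, safe to share across examples
settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.function_scoped_fixture])
settings.load_profile("ci")


@pytest.fixture
def config():
    return PipelineConfig()


def make_events(onsets, durations, drug="control", session="s1"):
    """Minimal EventLog for hand-built traces."""
    onsets = np.asarray(onsets, float)
    durations = np.asarray(durations, float)
    trials = pd.DataFrame({
        "trial_id": [f"t{i:02d}" for i in range(len(onsets))],
        "onset": onsets, "duration": durations, "session": session,
        "eye_treatment": "nondominant", "drug": drug,
    })
    trials["offset"] = trials["onset"] + trials["duration"]
    trials["nonstandard"] = False
    return EventLog(trials, pd.DataFrame(columns=["time", "button"]))


@pytest.fixture
def events_factory():
    return make_events
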