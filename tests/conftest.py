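import pytest

from epgkit.io import Event, Recording
from epgkit.simulate import builtin_profiles


def make_recording(segments, insect_id="test", duration_s=None):
    """Build a Recording from (code, duration_s) pairs tiling from 0."""
    events, t = [], 0.0
    for code, dur in segments:
        events.append(Event(code, t, t + dur))
        t += dur
    return Recording(
        insect_id=insect_id, events=events,
        duration_s=duration_s if duration_s is not None else t,
    )


@pytest.fixture(scope="session")
def profiles():
    return builtin_profiles()
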