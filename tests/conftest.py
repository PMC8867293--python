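import numpy as np
import pandas as pd
import pytest

from uemasim.banks import default_core_bank
from uemasim.metrics import EVENT_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(20210104)


@pytest.fixture
def core_bank():
    return default_core_bank()


class ScriptedRng:
    """Stands in for a numpy Generator, replaying scripted uniform draws
    (as raw values, clipped to the requested interval)."""

    def __init__(self, draws):
        self._draws = list(draws)

    def uniform(self, low, high):
        d = self._draws.pop(0) if self._draws else 0.0
        return min(max(d, low), np.nextafter(high, low))


@pytest.fixture
def scripted_rng():
    return ScriptedRng


def make_events(rows):
    """Build an event-log frame from compact dicts, filling defaults."""
    defaults = {
        "participant_id": "p001", "date": "2021-01-05",
        "prompt_id": "x", "timestamp": "2021-01-05T09:00:00",
        "scheduled_min": 540.0, "day_type": "uema", "slot_type": "core",
        "question_id": "int01", "category": "internal", "delivered": True,
        "status": "answered", "answer": "Yes", "latency_s": 4.0,
        "undo_used": False, "correct": None,
    }
    full = [{**defaults, **r} for r in rows]
    return pd.DataFrame(full, columns=EVENT_COLUMNS)


@pytest.fixture
def event_factory():
    return make_events
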