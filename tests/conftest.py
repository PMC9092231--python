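import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from multicrc.tables import CaptureHistoryTable, EventCountTable


@pytest.fixture
def worked_history() -> CaptureHistoryTable:
    """The 3-event worked example: 30 seen only at event 1, 80 only at
    event 2, 10 at all three."""
    return CaptureHistoryTable.from_counts({"100": 30, "010": 80, "111": 10}, k=3)


@pytest.fixture
def worked_event_counts() -> EventCountTable:
    """The same study in aggregate field format: event 1 total 40; event 2
    split 10 (holding the event-1 object) / 80 (not); event 3 cross-tab 10
    holding both prior objects, 0 elsewhere."""
    return EventCountTable.from_nested([
        {"": 40},
        {"1": 10, "0": 80},
        {"11": 10, "10": 0, "01": 0, "00": 0},
    ])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_table(rng: np.random.Generator, k: int, max_count: int = 50) -> CaptureHistoryTable:
    counts = rng.integers(0, max_count + 1, size=2 ** k - 1)
    if counts.sum() == 0:
        counts[0] = 1
    return CaptureHistoryTable(k=k, counts=counts)
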