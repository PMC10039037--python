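import numpy as np
import pytest

from actisleep.core import EpochGrid, SleepWakeSeries

START = "2024-01-01T22:00:00"


def series(labels, source="test", start=START, epoch_length_s=30):
    """Build a SleepWakeSeries from a 0/1 list."""
    labels = np.asarray(labels, dtype=np.uint8)
    return SleepWakeSeries(EpochGrid(start, len(labels), epoch_length_s), labels, source)


@pytest.fixture
def grid10():
    return EpochGrid(START, 10)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
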