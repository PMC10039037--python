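"""Core data model: raw recordings, epoch grids, hypnograms, sleep-wake series.

Sleep-wake labels are stored as ``uint8`` with ``SLEEP = 1`` and ``WAKE = 0``
(sleep is the positive class throughout the package). Epoch windows are
half-open ``[t, t + epoch_length_s)`` and anchored at the grid start time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, ParameterError

SLEEP: int = 1
WAKE: int = 0

#: PSG sleep-stage vocabulary (AASM). W is wake; everything else is sleep.
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "REM")


@dataclass(frozen=True)
class EpochGrid:
    """A uniform grid of non-overlapping scoring epochs.

    Parameters
    ----------
    start_time
        Absolute timestamp of the first epoch's left edge.
    n_epochs
        Number of epochs on the grid.
    epoch_length_s
        Epoch duration in seconds; must divide 60 so that per-minute
        endpoint conversions are exact.
    """

    start_time: pd.Timestamp
    n_epochs: int
    epoch_length_s: int = 30

    def __post_init__(self):
        object.__setattr__(self, "start_time", pd.Timestamp(self.start_time))
        if self.epoch_length_s <= 0 or 60 % self.epoch_length_s != 0:
            raise ParameterError(
                f"epoch_length_s must be a positive divisor of 60, got {self.epoch_length_s}"
            )
        if self.n_epochs < 0:
            raise ParameterError("n_epochs must be nonnegative")

    @property
    def epoch_timedelta(self) -> pd.Timedelta:
        return pd.Timedelta(seconds=self.epoch_length_s)

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + self.n_epochs * self.epoch_timedelta

    def timestamps(self) -> pd.DatetimeIndex:
        """Left edge of every epoch."""
        return pd.date_range(
            self.start_time, periods=self.n_epochs, freq=self.epoch_timedelta
        )

    def subgrid(self, start: int, n: int) -> "EpochGrid":
        if start < 0 or start + n > self.n_epochs:
            raise ParameterError("subgrid outside parent grid")
        return EpochGrid(
            self.start_time + start * self.epoch_timedelta, n, self.epoch_length_s
        )


@dataclass
class RawRecording:
    """Uniformly sampled tri-axial wrist acceleration in g (gravity included)."""

    subject_id: str
    start_time: pd.Timestamp
    sample_rate_hz: float
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self):
        self.start_time = pd.Timestamp(self.start_time)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (len(self.ax) == len(self.ay) == len(self.az)):
            raise DataError("axis sequences must have identical length")
        if len(self.ax) < 1:
            raise DataError("recording must contain at least one sample")
        if not self.sample_rate_hz > 0:
            raise ParameterError("sample_rate_hz must be positive")
        for name, a in (("ax", self.ax), ("ay", self.ay), ("az", self.az)):
            if not np.all(np.isfinite(a)):
                raise DataError(f"non-finite values in {name}")

    def __len__(self) -> int:
        return len(self.ax)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz

    def xyz(self) -> np.ndarray:
        """Samples as an ``(n, 3)`` array (columns x, y, z)."""
        return np.column_stack([self.ax, self.ay, self.az])

    def sample_times(self) -> pd.DatetimeIndex:
        dt = pd.Timedelta(seconds=1) / self.sample_rate_hz
        return self.start_time + dt * np.arange(len(self))


@dataclass
class Hypnogram:
    """PSG sleep stages, one label per epoch, drawn from W/N1/N2/N3/REM."""

    grid: EpochGrid
    stages: np.ndarray

    def __post_init__(self):
        self.stages = np.asarray(self.stages, dtype=object)
        if len(self.stages) != self.grid.n_epochs:
            raise DataError(
                f"{len(self.stages)} stages for a {self.grid.n_epochs}-epoch grid"
            )
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise DataError(f"unknown sleep stage labels: {sorted(map(str, bad))}")

    def __len__(self) -> int:
        return self.grid.n_epochs


@dataclass
class SleepWakeSeries:
    """Binary sleep/wake labels on an epoch grid (1 = sleep, 0 = wake)."""

    grid: EpochGrid
    labels: np.ndarray
    source: str = "unknown"

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.dtype == object or not np.isin(labels, (SLEEP, WAKE)).all():
            raise DataError("labels must be binary (0 = wake, 1 = sleep)")
        self.labels = labels.astype(np.uint8)
        if len(self.labels) != self.grid.n_epochs:
            raise DataError(
                f"{len(self.labels)} labels for a {self.grid.n_epochs}-epoch grid"
            )

    def __len__(self) -> int:
        return self.grid.n_epochs

    def sleep_epochs(self) -> int:
        return int(self.labels.sum())

    def with_labels(self, labels: np.ndarray, source: str | None = None) -> "SleepWakeSeries":
        return SleepWakeSeries(self.grid, labels, source or self.source)


def binarize_hypnogram(h: Hypnogram) -> SleepWakeSeries:
    """Collapse PSG stages to binary sleep/wake: W -> wake, N1/N2/N3/REM -> sleep."""
    labels = np.where(h.stages == "W", WAKE, SLEEP)
    return SleepWakeSeries(h.grid, labels, source="PSG")


def _series_timestamps(s) -> pd.DatetimeIndex:
    return s.grid.timestamps()


def align_to_grid(s, g: EpochGrid):
    """Restrict a :class:`SleepWakeSeries` or :class:`Hypnogram` to the epochs of *g*.

    Epochs are matched by their absolute left-edge timestamps; epochs outside
    the overlap are dropped. Raises :class:`AlignmentError` if the series and
    the grid share no epoch (including phase mismatch).
    """
    if s.grid.epoch_length_s != g.epoch_length_s:
        raise AlignmentError("epoch lengths differ")
    own = _series_timestamps(s)
    target = g.timestamps()
    common = own.intersection(target)
    if len(common) == 0:
        raise AlignmentError("series does not overlap the target grid")
    # overlap of two equal-phase uniform grids is contiguous
    start_idx = own.get_loc(common[0])
    out_grid = EpochGrid(common[0], len(common), g.epoch_length_s)
    sl = slice(start_idx, start_idx + len(common))
    if isinstance(s, Hypnogram):
        return Hypnogram(out_grid, s.stages[sl])
    return SleepWakeSeries(out_grid, s.labels[sl], s.source)


def align_pair(pred: SleepWakeSeries, truth: SleepWakeSeries) -> tuple[SleepWakeSeries, SleepWakeSeries]:
    """Put a prediction and a reference series on their common epoch grid."""
    a = align_to_grid(pred, truth.grid)
    b = align_to_grid(truth, a.grid)
    return align_to_grid(a, b.grid), b
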