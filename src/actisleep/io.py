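"""Delimited-text readers/writers and the raw-signal downsampling step.

File contracts
--------------
Acceleration: columns ``timestamp, x, y, z`` (names remappable), timestamp
ISO-8601 or epoch seconds, axes in g. Hypnogram: columns ``timestamp, stage``
with stage in W/N1/N2/N3/REM at 30-s spacing. Epoch-label files: columns
``timestamp, label, source`` with label in {sleep, wake}.

Recordings with internal gaps (spacing > 2x the median sample interval) are
rejected rather than imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import SLEEP, WAKE, EpochGrid, Hypnogram, RawRecording, SleepWakeSeries
from .errors import DataError, FormatError, GapError, ParameterError

DEFAULT_ACCEL_COLUMNS = {"timestamp": "timestamp", "x": "x", "y": "y", "z": "z"}

_LABEL_TO_INT = {"sleep": SLEEP, "wake": WAKE}
_INT_TO_LABEL = {SLEEP: "sleep", WAKE: "wake"}


def _parse_timestamps(col: pd.Series) -> pd.DatetimeIndex:
    if np.issubdtype(col.dtype, np.number):
        return pd.DatetimeIndex(pd.to_datetime(col.astype(float), unit="s"))
    try:
        return pd.DatetimeIndex(pd.to_datetime(col, format="ISO8601"))
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable timestamps: {exc}") from exc


def read_accel_csv(
    path,
    column_map: dict | None = None,
    delimiter: str = ",",
    subject_id: str | None = None,
) -> RawRecording:
    """Read a raw tri-axial acceleration file.

    The sample rate is inferred from the median timestamp spacing; no samples
    are dropped. Non-monotone timestamps raise :class:`DataError`, gaps larger
    than twice the median interval raise :class:`GapError` listing the gap
    locations.
    """
    cols = {**DEFAULT_ACCEL_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path, delimiter=delimiter)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns {missing} in {path}")
    t = _parse_timestamps(df[cols["timestamp"]])
    for axis in ("x", "y", "z"):
        if not np.issubdtype(df[cols[axis]].dtype, np.number):
            raise FormatError(f"column {cols[axis]!r} is not numeric")
    if len(t) > 1:
        dt = np.diff(t.asi8)  # ns
        if np.any(dt <= 0):
            raise DataError("timestamp column is not strictly increasing")
        median = np.median(dt)
        gaps = np.nonzero(dt > 2 * median)[0]
        if len(gaps):
            raise GapError(
                f"{len(gaps)} gap(s) > 2x sample interval at row(s) {gaps[:10].tolist()}",
                gap_indices=gaps,
            )
        rate = 1e9 / median
    else:
        rate = 1.0
    return RawRecording(
        subject_id=subject_id or str(path),
        start_time=t[0],
        sample_rate_hz=float(rate),
        ax=df[cols["x"]].to_numpy(float),
        ay=df[cols["y"]].to_numpy(float),
        az=df[cols["z"]].to_numpy(float),
    )


def write_accel_csv(r: RawRecording, path, delimiter: str = ",") -> None:
    df = pd.DataFrame(
        {
            "timestamp": r.sample_times(),
            "x": r.ax,
            "y": r.ay,
            "z": r.az,
        }
    )
    df.to_csv(path, sep=delimiter, index=False, date_format="%Y-%m-%dT%H:%M:%S.%f")


def read_hypnogram_csv(path, delimiter: str = ",", epoch_length_s: int = 30) -> Hypnogram:
    """Read a PSG hypnogram (one stage label per epoch row)."""
    df = pd.read_csv(path, delimiter=delimiter)
    for col in ("timestamp", "stage"):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    t = _parse_timestamps(df["timestamp"])
    stages = df["stage"].astype(str).str.strip().to_numpy(object)
    from .core import STAGES

    for i, s in enumerate(stages):
        if s not in STAGES:
            raise FormatError(f"unknown stage label {s!r} at row {i}")
    grid = EpochGrid(t[0], len(stages), epoch_length_s)
    return Hypnogram(grid, stages)


def write_hypnogram_csv(h: Hypnogram, path, delimiter: str = ",") -> None:
    pd.DataFrame({"timestamp": h.grid.timestamps(), "stage": h.stages}).to_csv(
        path, sep=delimiter, index=False, date_format="%Y-%m-%dT%H:%M:%S"
    )


def read_epochs_csv(path, delimiter: str = ",", epoch_length_s: int = 30) -> SleepWakeSeries:
    """Read a binary sleep/wake epoch file (columns timestamp, label, source)."""
    df = pd.read_csv(path, delimiter=delimiter)
    for col in ("timestamp", "label"):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path}")
    t = _parse_timestamps(df["timestamp"])
    labels = df["label"].astype(str).str.strip()
    bad = set(labels) - set(_LABEL_TO_INT)
    if bad:
        raise FormatError(f"unknown epoch labels: {sorted(bad)}")
    source = str(df["source"].iloc[0]) if "source" in df.columns and len(df) else "unknown"
    grid = EpochGrid(t[0], len(df), epoch_length_s)
    return SleepWakeSeries(grid, labels.map(_LABEL_TO_INT).to_numpy(), source)


def write_epochs_csv(s: SleepWakeSeries, path, delimiter: str = ",") -> None:
    pd.DataFrame(
        {
            "timestamp": s.grid.timestamps(),
            "label": [_INT_TO_LABEL[v] for v in s.labels],
            "source": s.source,
        }
    ).to_csv(path, sep=delimiter, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def downsample_mean(
    r: RawRecording, target_rate_hz: float = 40.0, window_ms: float = 25.0
) -> RawRecording:
    """Downsample by block-averaging in fixed half-open time windows.

    Each output sample is the arithmetic mean of the input samples whose
    timestamps fall in ``[k*w, (k+1)*w)`` with ``w = window_ms``. The trailing
    window is dropped unless fully covered by the recording. This is the
    standard preprocessing step that brings an ~85.7 Hz wrist recording onto
    the 40 Hz grid the count algorithm expects.
    """
    if not np.isclose(target_rate_hz * window_ms, 1000.0, rtol=1e-6):
        raise ParameterError(
            f"target_rate_hz ({target_rate_hz}) and window_ms ({window_ms}) are inconsistent"
        )
    if r.sample_rate_hz < target_rate_hz:
        raise ParameterError(
            f"cannot downsample from {r.sample_rate_hz} Hz to {target_rate_hz} Hz (upsampling)"
        )
    w = window_ms / 1000.0
    t = np.arange(len(r)) / r.sample_rate_hz
    idx = np.floor(t / w + 1e-9).astype(np.int64)  # eps guards 1/rate rounding
    # keep only windows fully covered by the recording duration
    n_windows = int(np.floor(r.duration_s / w + 1e-9))
    keep = idx < n_windows
    idx = idx[keep]
    counts = np.bincount(idx, minlength=n_windows)
    if np.any(counts == 0):  # slower than target rate inside tolerance band
        raise ParameterError("input rate too low: empty averaging windows")

    def _mean(a: np.ndarray) -> np.ndarray:
        return np.bincount(idx, weights=a[keep], minlength=n_windows) / counts

    return RawRecording(
        subject_id=r.subject_id,
        start_time=r.start_time,
        sample_rate_hz=target_rate_hz,
        ax=_mean(r.ax),
        ay=_mean(r.ay),
        az=_mean(r.az),
    )
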