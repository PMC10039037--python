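"""Activity-count derivation from 40 Hz wrist acceleration.

Activity counts are the legacy input unit of actigraphy: a per-epoch integer
summarizing band-pass-filtered, rectified, thresholded acceleration. The
implementation follows the published reverse-engineering of the ActiGraph
counts chain (Brønd et al. 2017, Med Sci Sports Exerc; Neishabouri et al.
2022, Sci Rep):

1. anti-aliased polyphase resampling of the 40 Hz signal to the filter's
   native 30 Hz rate;
2. a fixed IIR band-pass filter (Butterworth, 0.25-2.5 Hz at 30 Hz)
   emulating the legacy analog band, applied per axis with DC-steady
   initial conditions so gravity is rejected from the first sample;
3. rectification, saturation at ``CEILING_G`` (2.13 g), dead-band below
   ``DEADBAND_G`` (0.068 g), quantization at 8-bit resolution
   (``CEILING_G / 128`` g per unit);
4. decimation to 10 Hz (every third sample) and per-epoch accumulation on
   the 30-s grid, dropping a trailing partial epoch.

The chain up to quantization is linear in the input amplitude, so per-epoch
counts are non-decreasing in oscillation amplitude and saturate exactly once
every retained sample hits the ceiling. A constant (gravity-only) signal is
removed by the band-pass stage and yields zero counts.

``backend="agcounts"`` delegates to the open-source reference package when it
is importable, for cross-validation of the internal chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, lfilter, lfilter_zi, resample_poly

from .core import EpochGrid, RawRecording
from .errors import ParameterError

NATIVE_RATE_HZ = 30.0
OUTPUT_RATE_HZ = 10.0
CEILING_G = 2.13
DEADBAND_G = 0.068
RESOLUTION_G = CEILING_G / 128.0  # 8-bit quantization step

# Band edges of the legacy analog acquisition band, Hz.
BAND_HZ = (0.25, 2.5)
_BPF_ORDER = 3

_BPF_B, _BPF_A = butter(
    _BPF_ORDER, [2 * f / NATIVE_RATE_HZ for f in BAND_HZ], btype="bandpass"
)


@dataclass
class CountSeries:
    """Per-axis nonnegative integer activity counts on a 30-s epoch grid.

    ``warmup_epochs`` flags how many leading epochs include the filter
    warm-up transient (computed on zero-padded history).
    """

    grid: EpochGrid
    counts: np.ndarray  # (n_epochs, 3) int64, columns x, y, z
    warmup_epochs: int = 1

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 3:
            raise ParameterError("counts must be an (n_epochs, 3) array")
        if self.counts.shape[0] != self.grid.n_epochs:
            raise ParameterError("counts rows must match grid.n_epochs")
        if np.any(self.counts < 0):
            raise ParameterError("counts must be nonnegative")
        self.counts = self.counts.astype(np.int64)

    @property
    def cx(self) -> np.ndarray:
        return self.counts[:, 0]

    @property
    def cy(self) -> np.ndarray:
        return self.counts[:, 1]

    @property
    def cz(self) -> np.ndarray:
        return self.counts[:, 2]


@dataclass(frozen=True)
class AxisCombineMode:
    """How to collapse tri-axial counts to the scalar series classifiers use."""

    mode: str  # single_axis | vector_magnitude | sixth_root_sum_squares
    axis: str | None = None

    def __post_init__(self):
        if self.mode not in ("single_axis", "vector_magnitude", "sixth_root_sum_squares"):
            raise ParameterError(f"unknown axis-combination mode {self.mode!r}")
        if self.mode == "single_axis" and self.axis not in ("x", "y", "z"):
            raise ParameterError("single_axis requires axis in {'x','y','z'}")


def _quantize(filtered: np.ndarray) -> np.ndarray:
    """Rectify, clip, dead-band and quantize a filtered axis to count units."""
    x = np.abs(np.clip(filtered, -CEILING_G, CEILING_G))
    x[x < DEADBAND_G] = 0.0
    return np.floor(x / RESOLUTION_G + 1e-12)


def _axis_counts_30hz(x30: np.ndarray, epoch_samples_10hz: int) -> np.ndarray:
    zi = lfilter_zi(_BPF_B, _BPF_A) * x30[0]
    filtered, _ = lfilter(_BPF_B, _BPF_A, x30, zi=zi)
    units = _quantize(filtered)[:: int(NATIVE_RATE_HZ / OUTPUT_RATE_HZ)]
    n_epochs = len(units) // epoch_samples_10hz
    units = units[: n_epochs * epoch_samples_10hz]
    return units.reshape(n_epochs, epoch_samples_10hz).sum(axis=1).astype(np.int64)


def compute_counts(
    r: RawRecording,
    epoch_length_s: int = 30,
    backend: str = "internal",
    rate_tolerance_hz: float = 0.1,
) -> CountSeries:
    """Compute per-axis activity counts in fixed epochs from 40 Hz acceleration.

    Raises :class:`ParameterError` if the input is not on the 40 Hz grid;
    bring raw recordings there first with :func:`actisleep.io.downsample_mean`.
    """
    if abs(r.sample_rate_hz - 40.0) > rate_tolerance_hz:
        raise ParameterError(
            f"compute_counts expects 40 Hz input, got {r.sample_rate_hz} Hz; "
            "apply actisleep.io.downsample_mean first"
        )
    if backend == "agcounts":
        return _agcounts_backend(r, epoch_length_s)
    if backend != "internal":
        raise ParameterError(f"unknown counts backend {backend!r}")
    n_eps = int(OUTPUT_RATE_HZ) * epoch_length_s
    cols = []
    for axis in (r.ax, r.ay, r.az):
        x30 = resample_poly(axis, up=3, down=4, padtype="line")
        cols.append(_axis_counts_30hz(x30, n_eps))
    n_epochs = min(len(c) for c in cols)
    counts = np.column_stack([c[:n_epochs] for c in cols])
    grid = EpochGrid(r.start_time, n_epochs, epoch_length_s)
    return CountSeries(grid, counts)


def _agcounts_backend(r: RawRecording, epoch_length_s: int) -> CountSeries:
    try:
        from agcounts.extract import get_counts
    except ImportError as exc:  # pragma: no cover - reference package optional
        raise ImportError(
            "the 'agcounts' reference backend is not installed; "
            "use backend='internal'"
        ) from exc
    raw = r.xyz()
    counts = get_counts(raw, freq=int(round(r.sample_rate_hz)), epoch=epoch_length_s)
    grid = EpochGrid(r.start_time, counts.shape[0], epoch_length_s)
    return CountSeries(grid, counts)


def combine_axes(c: CountSeries, mode: AxisCombineMode | str = "vector_magnitude") -> np.ndarray:
    """Collapse tri-axial counts to one scalar value per epoch.

    ``vector_magnitude`` is sqrt(cx^2+cy^2+cz^2); ``sixth_root_sum_squares``
    is (cx^2+cy^2+cz^2)^(1/6), the compressive combination used for
    count-sequence models trained on proprietary counts.
    """
    if isinstance(mode, str):
        mode = AxisCombineMode(mode) if mode != "single_axis" else AxisCombineMode(mode, "x")
    sq = (c.counts.astype(float) ** 2).sum(axis=1)
    if mode.mode == "single_axis":
        return {"x": c.cx, "y": c.cy, "z": c.cz}[mode.axis].astype(float)
    if mode.mode == "vector_magnitude":
        return np.sqrt(sq)
    return np.power(sq, 1.0 / 6.0)
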