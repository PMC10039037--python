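"""Sleep-wake classifiers: windowed linear models, Sadeh, Sazonov, z-angle.

All count-based classifiers consume a scalar per-epoch count series on the
30-s grid. Models trained on 1-minute epochs (Cole-Kripke, Oakley, Sadeh)
aggregate 30-s counts to minutes by pairwise summation, classify on the
minute basis, and broadcast each decision back to its constituent 30-s
epochs, so every classifier emits exactly one label per 30-s epoch.
Out-of-range window epochs read as zero counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import SLEEP, EpochGrid, RawRecording, SleepWakeSeries
from .errors import AlignmentError, ParameterError
from .presets import load_presets


# ---------------------------------------------------------------------------
# windowed linear models (Cole-Kripke, Oakley, plain count threshold)

@dataclass
class LinearWindowModel:
    """A weighted-window score ``D = scale * sum_o w(o) * A(t+o)`` with a
    sleep threshold; the classic shape of the legacy regression scorers."""

    name: str
    weights: dict[int, float]
    scale: float = 1.0
    threshold: float = 1.0
    sleep_when: str = "score_below"  # or score_at_or_below
    epoch_basis_s: int = 60

    def __post_init__(self):
        if not self.weights:
            raise ParameterError("weights must be non-empty")
        if self.sleep_when not in ("score_below", "score_at_or_below"):
            raise ParameterError(f"bad sleep_when {self.sleep_when!r}")
        if self.epoch_basis_s not in (30, 60):
            raise ParameterError("epoch_basis_s must be 30 or 60")
        if not np.isfinite(self.threshold):
            raise ParameterError("threshold must be finite")

    @classmethod
    def from_preset(cls, name: str, presets: dict | None = None) -> "LinearWindowModel":
        p = (presets or load_presets())[name]
        return cls(
            name=name,
            weights={int(k): float(v) for k, v in p["weights"].items()},
            scale=float(p["scale"]),
            threshold=float(p["threshold"]),
            sleep_when=p["sleep_when"],
            epoch_basis_s=int(p["epoch_basis_s"]),
        )


def count_threshold_model(threshold: float = 0.0, name: str = "count_threshold") -> LinearWindowModel:
    """Single-epoch thresholding: sleep when the epoch's counts <= threshold."""
    return LinearWindowModel(
        name=name, weights={0: 1.0}, scale=1.0, threshold=threshold,
        sleep_when="score_at_or_below", epoch_basis_s=30,
    )


def _check_counts(counts: np.ndarray, grid: EpochGrid) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or len(counts) == 0:
        raise ParameterError("counts must be a non-empty 1-d series")
    if grid.epoch_length_s != 30:
        raise ParameterError("classifiers expect a 30-s epoch grid")
    if len(counts) != grid.n_epochs:
        raise AlignmentError("counts length does not match grid")
    return counts


def _to_minutes(counts: np.ndarray) -> np.ndarray:
    """Aggregate 30-s counts to 1-min epochs by pairwise sum (odd tail kept)."""
    n = len(counts)
    padded = np.concatenate([counts, [0.0]]) if n % 2 else counts
    return padded.reshape(-1, 2).sum(axis=1)


def _broadcast_minutes(minute_labels: np.ndarray, n_epochs_30s: int) -> np.ndarray:
    return np.repeat(minute_labels, 2)[:n_epochs_30s]


def _windowed_score(counts: np.ndarray, weights: dict[int, float], scale: float) -> np.ndarray:
    n = len(counts)
    score = np.zeros(n)
    for off, w in weights.items():
        shifted = np.zeros(n)
        if off >= 0:
            shifted[: n - off if off else n] = counts[off:]
        else:
            shifted[-off:] = counts[:off]
        score += w * shifted
    return scale * score


def classify_linear_window(
    counts: np.ndarray, m: LinearWindowModel, grid: EpochGrid
) -> SleepWakeSeries:
    counts = _check_counts(counts, grid)
    basis = _to_minutes(counts) if m.epoch_basis_s == 60 else counts
    score = _windowed_score(basis, m.weights, m.scale)
    if m.sleep_when == "score_below":
        sleep = score < m.threshold
    else:
        sleep = score <= m.threshold
    labels = sleep.astype(np.uint8)
    if m.epoch_basis_s == 60:
        labels = _broadcast_minutes(labels, grid.n_epochs)
    return SleepWakeSeries(grid, labels, source=m.name)


# ---------------------------------------------------------------------------
# Sadeh

@dataclass
class SadehParams:
    intercept: float = 7.601
    w_mean: float = -0.065
    w_nat: float = -1.08
    w_sd: float = -0.056
    w_log: float = -0.703
    nat_low: float = 50.0
    nat_high: float = 100.0
    window_epochs_each_side: int = 5
    sd_window_epochs: int = 6
    sleep_threshold: float = 0.0

    def __post_init__(self):
        if not self.nat_low < self.nat_high:
            raise ParameterError("nat_low must be < nat_high")
        if self.window_epochs_each_side < 1 or self.sd_window_epochs < 1:
            raise ParameterError("window sizes must be >= 1")

    @classmethod
    def from_preset(cls, presets: dict | None = None) -> "SadehParams":
        p = (presets or load_presets())["sadeh"]
        return cls(
            intercept=p["intercept"], w_mean=p["w_mean"], w_nat=p["w_nat"],
            w_sd=p["w_sd"], w_log=p["w_log"], nat_low=p["nat_low"],
            nat_high=p["nat_high"],
            window_epochs_each_side=p["window_epochs_each_side"],
            sd_window_epochs=p["sd_window_epochs"],
            sleep_threshold=p["sleep_threshold"],
        )


def classify_sadeh(counts: np.ndarray, p: SadehParams, grid: EpochGrid) -> SleepWakeSeries:
    """Sadeh probability-of-sleep score on the 1-minute basis.

    PS = intercept + w_mean*MW5 + w_nat*NAT + w_sd*SD6 + w_log*LG, where MW5
    is the mean count in the centered 11-min window, NAT the number of window
    minutes with counts in [nat_low, nat_high), SD6 the standard deviation of
    the current and preceding 5 minutes, and LG = ln(current + 1). Sleep when
    PS >= sleep_threshold. Minutes outside the record read as zero counts.
    """
    counts = _check_counts(counts, grid)
    mins = _to_minutes(counts)
    k = p.window_epochs_each_side
    n = len(mins)
    padded = np.concatenate([np.zeros(k), mins, np.zeros(k)])
    win = np.lib.stride_tricks.sliding_window_view(padded, 2 * k + 1)
    mw5 = win.mean(axis=1)
    nat = ((win >= p.nat_low) & (win < p.nat_high)).sum(axis=1)
    sd_pad = np.concatenate([np.zeros(p.sd_window_epochs - 1), mins])
    sd_win = np.lib.stride_tricks.sliding_window_view(sd_pad, p.sd_window_epochs)
    sd6 = sd_win.std(axis=1)
    lg = np.log(mins + 1.0)
    ps = p.intercept + p.w_mean * mw5 + p.w_nat * nat + p.w_sd * sd6 + p.w_log * lg
    labels = _broadcast_minutes((ps >= p.sleep_threshold).astype(np.uint8), grid.n_epochs)
    return SleepWakeSeries(grid, labels, source="sadeh")


# ---------------------------------------------------------------------------
# Sazonov

@dataclass
class SazonovParams:
    intercept: float = 1.727
    window_weights: dict[int, float] = field(
        default_factory=lambda: {1: -0.256, 2: -0.154, 3: -0.136, 4: -0.140, 5: -0.176}
    )
    probability_threshold: float = 0.5

    def __post_init__(self):
        if not self.window_weights:
            raise ParameterError("at least one trailing window required")
        if not 0.0 < self.probability_threshold < 1.0:
            raise ParameterError("probability_threshold must be in (0, 1)")

    @classmethod
    def from_preset(cls, presets: dict | None = None) -> "SazonovParams":
        p = (presets or load_presets())["sazonov"]
        return cls(
            intercept=p["intercept"],
            window_weights={int(k): float(v) for k, v in p["window_weights"].items()},
            probability_threshold=p["probability_threshold"],
        )


def classify_sazonov(counts: np.ndarray, p: SazonovParams, grid: EpochGrid) -> SleepWakeSeries:
    """Logistic score on trailing-window count maxima; sleep when
    logistic(score) >= probability_threshold."""
    counts = _check_counts(counts, grid)
    n = len(counts)
    score = np.full(n, p.intercept)
    for w, weight in p.window_weights.items():
        padded = np.concatenate([np.zeros(w - 1), counts])
        trail_max = np.lib.stride_tricks.sliding_window_view(padded, w).max(axis=1)
        score += weight * trail_max
    prob = expit(score)
    return SleepWakeSeries(grid, (prob >= p.probability_threshold).astype(np.uint8),
                           source="sazonov")


# ---------------------------------------------------------------------------
# van Hees z-angle heuristic

@dataclass
class VanHeesParams:
    median_window_s: float = 5.0
    angle_block_s: float = 5.0
    angle_change_threshold_deg: float = 5.0
    min_still_duration_min: float = 5.0

    def __post_init__(self):
        if min(self.median_window_s, self.angle_block_s,
               self.angle_change_threshold_deg, self.min_still_duration_min) <= 0:
            raise ParameterError("all van Hees parameters must be positive")
        if self.min_still_duration_min < self.angle_block_s / 60.0:
            raise ParameterError("min_still_duration_min shorter than one block")

    @classmethod
    def from_preset(cls, presets: dict | None = None) -> "VanHeesParams":
        p = (presets or load_presets())["vanhees"]
        return cls(
            median_window_s=p["median_window_s"],
            angle_block_s=p["angle_block_s"],
            angle_change_threshold_deg=p["angle_change_threshold_deg"],
            min_still_duration_min=p["min_still_duration_min"],
        )


def _z_angle_deg(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    horiz = np.sqrt(x * x + y * y)
    zero = (horiz == 0) & (z == 0)
    if np.any(zero):
        warnings.warn("all-zero acceleration vector: z-angle undefined, using 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        ang = np.degrees(np.arctan2(z, horiz))
    ang[zero] = 0.0
    return ang


def compute_z_angle(r: RawRecording, p: VanHeesParams) -> tuple[np.ndarray, EpochGrid]:
    """Forearm elevation angle per consecutive block, in degrees.

    Per-axis rolling medians over ``median_window_s`` suppress transients,
    the z-angle atan(z / sqrt(x^2 + y^2)) is taken per sample, then averaged
    over consecutive ``angle_block_s`` blocks. Scale-invariant: multiplying
    the input by a positive constant leaves the angle unchanged. Returns the
    block values and the block grid they live on.
    """
    w = max(1, int(round(p.median_window_s * r.sample_rate_hz)))
    med = [
        pd.Series(a).rolling(w, center=True, min_periods=1).median().to_numpy()
        for a in (r.ax, r.ay, r.az)
    ]
    ang = _z_angle_deg(*med)
    t = np.arange(len(r)) / r.sample_rate_hz
    idx = np.floor(t / p.angle_block_s + 1e-9).astype(np.int64)
    n_blocks = int(np.floor(r.duration_s / p.angle_block_s + 1e-9))
    keep = idx < n_blocks
    sums = np.bincount(idx[keep], weights=ang[keep], minlength=n_blocks)
    nums = np.bincount(idx[keep], minlength=n_blocks)
    blocks = sums / np.maximum(nums, 1)
    block_grid = EpochGrid(r.start_time, n_blocks, int(p.angle_block_s))
    return blocks, block_grid


def classify_vanhees(
    angles: np.ndarray, p: VanHeesParams, grid: EpochGrid,
    block_grid: EpochGrid | None = None,
) -> SleepWakeSeries:
    """Sustained-posture sleep detection on block z-angles.

    Maximal runs of blocks whose successive absolute angle changes stay below
    ``angle_change_threshold_deg`` and that last at least
    ``min_still_duration_min`` are labeled sleep; everything else is wake.
    Block labels are resampled to 30-s epochs by majority (ties -> wake).
    """
    angles = np.asarray(angles, dtype=float)
    n = len(angles)
    if n == 0:
        raise AlignmentError("empty angle series")
    still_labels = np.zeros(n, dtype=np.uint8)
    small = np.abs(np.diff(angles)) < p.angle_change_threshold_deg
    min_blocks = int(np.ceil(p.min_still_duration_min * 60.0 / p.angle_block_s))
    # maximal runs of blocks connected by small changes
    start = 0
    for i in range(n):
        if i == n - 1 or not small[i]:
            if i - start + 1 >= min_blocks:
                still_labels[start : i + 1] = SLEEP
            start = i + 1
    if block_grid is None:
        block_grid = EpochGrid(grid.start_time, n, int(p.angle_block_s))
    # map blocks onto the epoch grid by their midpoint timestamps
    block_mid_s = (
        (block_grid.start_time - grid.start_time).total_seconds()
        + (np.arange(n) + 0.5) * p.angle_block_s
    )
    epoch_idx = np.floor(block_mid_s / grid.epoch_length_s).astype(np.int64)
    valid = (epoch_idx >= 0) & (epoch_idx < grid.n_epochs)
    covered = np.unique(epoch_idx[valid])
    if len(covered) < grid.n_epochs:
        raise AlignmentError("angle blocks do not cover the epoch grid")
    sleep_votes = np.bincount(epoch_idx[valid], weights=still_labels[valid],
                              minlength=grid.n_epochs)
    total_votes = np.bincount(epoch_idx[valid], minlength=grid.n_epochs)
    labels = (sleep_votes > total_votes / 2.0).astype(np.uint8)  # tie -> wake
    return SleepWakeSeries(grid, labels, source="vanhees")


def classify_vanhees_from_raw(
    r: RawRecording, grid: EpochGrid, p: VanHeesParams | None = None
) -> SleepWakeSeries:
    """Convenience: raw recording -> z-angle blocks -> sleep/wake on *grid*."""
    p = p or VanHeesParams()
    angles, block_grid = compute_z_angle(r, p)
    return classify_vanhees(angles, p, grid, block_grid)


# ---------------------------------------------------------------------------
# dataset-independent reference classifiers

def reference_classifier(grid: EpochGrid, mode: str) -> SleepWakeSeries:
    """Constant all-sleep / all-wake baselines (performance floor/ceiling rows)."""
    if grid.n_epochs < 1:
        raise ParameterError("grid must contain at least one epoch")
    if mode == "all_sleep":
        return SleepWakeSeries(grid, np.ones(grid.n_epochs, dtype=np.uint8), "all_sleep")
    if mode == "all_wake":
        return SleepWakeSeries(grid, np.zeros(grid.n_epochs, dtype=np.uint8), "all_wake")
    raise ParameterError(f"unknown reference mode {mode!r}")
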