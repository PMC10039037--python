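"""Random-forest sleep-wake harness on raw-acceleration epoch features.

This is a trainable feature extractor + model harness in the spirit of the
published raw-acceleration forests (per-epoch summary statistics with lag and
lead context), not a reproduction of any published trained forest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .core import EpochGrid, RawRecording, SleepWakeSeries
from .errors import AlignmentError, ParameterError, TrainingError

_BASE_FEATURES = (
    "ax_mean", "ax_sd", "ax_min", "ax_max",
    "ay_mean", "ay_sd", "ay_min", "ay_max",
    "az_mean", "az_sd", "az_min", "az_max",
    "vm_mean", "vm_sd", "zangle_mean", "zangle_sd",
)
_SHIFTS = (0, -1, 1, -2, 2)  # base, lag1, lead1, lag2, lead2


@dataclass
class RFFeatureTable:
    grid: EpochGrid
    feature_names: list[str]
    values: np.ndarray  # (n_epochs, n_features)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_epochs, len(self.feature_names)):
            raise ParameterError("feature matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("non-finite feature values")


def _shift_name(base: str, shift: int) -> str:
    if shift == 0:
        return base
    return f"{base}_{'lag' if shift < 0 else 'lead'}{abs(shift)}"


def extract_rf_features(r: RawRecording, grid: EpochGrid) -> RFFeatureTable:
    """Per-epoch signal summaries with +/-2-epoch context columns.

    Base features per 30-s epoch: per-axis mean/SD/min/max, vector-magnitude
    mean/SD, z-angle mean/SD. Lag/lead copies are zero-padded at the record
    boundaries. Column order is deterministic.
    """
    t = (r.start_time - grid.start_time).total_seconds() + np.arange(len(r)) / r.sample_rate_hz
    idx = np.floor(t / grid.epoch_length_s + 1e-9).astype(np.int64)
    valid = (idx >= 0) & (idx < grid.n_epochs)
    if len(np.unique(idx[valid])) < grid.n_epochs:
        raise AlignmentError("recording does not cover the epoch grid")
    vm = np.sqrt(r.ax**2 + r.ay**2 + r.az**2)
    with np.errstate(invalid="ignore"):
        zang = np.degrees(np.arctan2(r.az, np.sqrt(r.ax**2 + r.ay**2)))
    base = np.empty((grid.n_epochs, len(_BASE_FEATURES)))
    col = 0
    for sig, stats in (
        (r.ax, "full"), (r.ay, "full"), (r.az, "full"), (vm, "meansd"), (zang, "meansd"),
    ):
        s = sig[valid]
        i = idx[valid]
        n = np.bincount(i, minlength=grid.n_epochs).astype(float)
        mean = np.bincount(i, weights=s, minlength=grid.n_epochs) / n
        sq = np.bincount(i, weights=s * s, minlength=grid.n_epochs) / n
        sd = np.sqrt(np.maximum(sq - mean**2, 0.0))
        base[:, col] = mean
        base[:, col + 1] = sd
        col += 2
        if stats == "full":
            mn = np.full(grid.n_epochs, np.inf)
            mx = np.full(grid.n_epochs, -np.inf)
            np.minimum.at(mn, i, s)
            np.maximum.at(mx, i, s)
            base[:, col] = mn
            base[:, col + 1] = mx
            col += 2
    names, cols = [], []
    for shift in _SHIFTS:
        shifted = np.zeros_like(base)
        if shift == 0:
            shifted = base
        elif shift < 0:
            shifted[-shift:] = base[:shift]
        else:
            shifted[:-shift] = base[shift:]
        cols.append(shifted)
        names.extend(_shift_name(b, shift) for b in _BASE_FEATURES)
    return RFFeatureTable(grid, names, np.hstack(cols))


def train_rf(
    features: RFFeatureTable, truth: SleepWakeSeries,
    seed: int = 0, n_estimators: int = 100,
) -> RandomForestClassifier:
    """Fit a seeded random forest on aligned epoch features and PSG truth."""
    if features.grid.n_epochs != truth.grid.n_epochs or (
        features.grid.start_time != truth.grid.start_time
    ):
        raise AlignmentError("features and truth are not on the same grid")
    y = truth.labels
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    model.fit(features.values, y)
    return model


def apply_rf(features: RFFeatureTable, model) -> SleepWakeSeries:
    if model is None:
        raise ParameterError("apply requires a trained model; call train_rf first")
    labels = np.asarray(model.predict(features.values), dtype=np.uint8)
    return SleepWakeSeries(features.grid, labels, source="random_forest")


def train_apply_rf(
    features: RFFeatureTable, truth: SleepWakeSeries | None = None,
    model=None, seed: int = 0,
) -> SleepWakeSeries:
    """Train on *truth* (if given) then predict on the feature grid."""
    if model is None:
        if truth is None:
            raise ParameterError("either a truth series or a trained model is required")
        model = train_rf(features, truth, seed=seed)
    return apply_rf(features, model)
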