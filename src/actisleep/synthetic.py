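"""Synthetic paired PSG hypnograms and raw wrist acceleration.

The generator produces the statistical structure the evaluation framework
assumes, so the full pipeline can be exercised without a clinical dataset:

* a two-state alternating bout sequence (starting in wake) with geometric
  bout lengths, emitted as W for wake and a fixed repeating N1/N2/N3/N2/REM
  pattern for sleep so stage binarization is exercised;
* wake epochs carry sustained band-limited (0.5-3 Hz) wrist movement plus
  orientation changes: a posture shift at every wake-bout start and every
  ``posture_shift_period_min`` thereafter, with additional per-block (5-s)
  orientation dither mimicking restless wakefulness;
* sleep epochs are static at the last adopted posture apart from sensor
  noise, with a probability ``sleep_residual_movement_prob`` per epoch of a
  20-s movement burst emulating disturbed sleepers;
* gravity is always present; output is tri-axial acceleration in g at
  ``sample_rate_hz`` (default 85.7).

All randomness derives from one master seed; nights are reproducible from
``(seed, subject_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EpochGrid, Hypnogram, RawRecording
from .errors import ParameterError
from .evaluation import SleepEndpoints

_SLEEP_STAGE_CYCLE = ("N1", "N2", "N3", "N2", "REM")
_BURST_DURATION_S = 20.0
_DITHER_BLOCK_S = 5.0
_EDGE_TAPER_S = 0.5
# movement stops this long before an epoch boundary so the count filter's
# causal tail (~1.3 s above dead-band) dies out inside the epoch it belongs to
_MOVEMENT_GAP_S = 2.0


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort (defaults: 28 subjects,
    one 8-h night each, ~70% sleep, mixed-pathology level of disturbance)."""

    n_subjects: int = 28
    night_duration_min: float = 480.0
    epoch_length_s: int = 30
    sleep_bout_mean_min: float = 35.0
    wake_bout_mean_min: float = 15.0
    #: shortest sleep bout emitted; sleep bouts are floor-shifted geometric so
    #: the night is made of consolidated, scorable sleep periods rather than
    #: single-epoch stage flickers (wake bouts keep the plain geometric law)
    min_sleep_bout_min: float = 5.0
    wake_movement_amplitude_g: float = 0.5
    sleep_residual_movement_prob: float = 0.05
    posture_shift_period_min: float = 2.0
    sensor_noise_sd_g: float = 0.01
    sample_rate_hz: float = 85.7
    seed: int = 0
    start_time: str = "2024-01-01T22:00:00"

    def __post_init__(self):
        if self.night_duration_min <= 0:
            raise ParameterError("night duration must be positive")
        if min(self.sleep_bout_mean_min, self.wake_bout_mean_min,
               self.wake_movement_amplitude_g, self.posture_shift_period_min) <= 0:
            raise ParameterError("rates and durations must be positive")
        if not 0.0 <= self.sleep_residual_movement_prob <= 1.0:
            raise ParameterError("sleep_residual_movement_prob must be in [0, 1]")
        if self.sensor_noise_sd_g < 0:
            raise ParameterError("sensor_noise_sd_g must be nonnegative")

    @property
    def n_epochs(self) -> int:
        return int(np.floor(self.night_duration_min * 60.0 / self.epoch_length_s))


@dataclass
class GroundTruth:
    """A generated hypnogram with its analytically derived endpoints."""

    hypnogram: Hypnogram
    endpoints: SleepEndpoints
    subject_id: str = ""
    subject_index: int = 0


def _rng(c: SynthConfig, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(c.seed), spawn_key=(subject_index, stream))
    )


def _analytic_endpoints(sleep: np.ndarray, epoch_length_s: int) -> SleepEndpoints:
    ep_min = epoch_length_s / 60.0
    idx = np.nonzero(sleep)[0]
    n_sleep = len(idx)
    tst = n_sleep * ep_min
    se = 100.0 * n_sleep / len(sleep)
    if n_sleep == 0:
        return SleepEndpoints(None, 0.0, 0.0, None, None)
    onset, offset = int(idx[0]), int(idx[-1])
    waso = float((offset - onset + 1) - n_sleep) * ep_min
    return SleepEndpoints(waso, tst, se, onset, offset)


def gen_hypnogram(c: SynthConfig, subject_index: int) -> GroundTruth:
    """Generate one night's ground-truth hypnogram, starting in wake."""
    n = c.n_epochs
    if n < 1:
        raise ParameterError("night too short for a single epoch")
    rng = _rng(c, subject_index, 0)
    per_epoch_min = c.epoch_length_s / 60.0
    mean_wake = c.wake_bout_mean_min / per_epoch_min
    mean_sleep = c.sleep_bout_mean_min / per_epoch_min
    floor_sleep = max(1, int(round(c.min_sleep_bout_min / per_epoch_min)))
    if mean_sleep < floor_sleep:
        raise ParameterError("sleep_bout_mean_min below the minimum bout duration")
    p_wake = min(1.0, 1.0 / mean_wake)
    # floor-shifted geometric keeps the configured mean bout length
    p_sleep = min(1.0, 1.0 / (mean_sleep - floor_sleep + 1))
    sleep = np.zeros(n, dtype=bool)
    pos, in_sleep = 0, False
    while pos < n:
        if in_sleep:
            bout = floor_sleep - 1 + int(rng.geometric(p_sleep))
        else:
            bout = int(rng.geometric(p_wake))
        sleep[pos : pos + bout] = in_sleep
        pos += bout
        in_sleep = not in_sleep
    stages = np.empty(n, dtype=object)
    stages[~sleep] = "W"
    cycle = np.array(_SLEEP_STAGE_CYCLE, dtype=object)
    stages[sleep] = cycle[np.arange(int(sleep.sum())) % len(cycle)]
    grid = EpochGrid(np.datetime64(c.start_time), n, c.epoch_length_s)
    return GroundTruth(
        hypnogram=Hypnogram(grid, stages),
        endpoints=_analytic_endpoints(sleep, c.epoch_length_s),
        subject_id=f"synth{subject_index:03d}",
        subject_index=subject_index,
    )


def _random_orientation(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.standard_normal(3)
        norm = np.linalg.norm(v)
        if norm > 1e-3:
            return v / norm


def _taper(n: int, ramp_n: int) -> np.ndarray:
    env = np.ones(n)
    r = min(ramp_n, n // 2)
    if r > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = ramp
        env[-r:] = ramp[::-1]
    return env


def _block_edges(n: int, fs: float, block_s: float) -> np.ndarray:
    """Sample indices cutting ``n`` samples into ~block_s blocks, the last
    edge pinned to ``n`` so no stray sliver block is produced."""
    n_blocks = max(1, int(round(n / (fs * block_s))))
    edges = np.round(np.arange(n_blocks + 1) * n / n_blocks).astype(int)
    return edges


def _oscillation(rng: np.random.Generator, n: int, fs: float, amp: float) -> np.ndarray:
    """Band-limited (0.5-3 Hz) tapered oscillation along a random direction,
    confined to its own window so counts do not leak across epochs."""
    f = rng.uniform(0.5, 3.0)
    phase = rng.uniform(0, 2 * np.pi)
    d = _random_orientation(rng)
    t = np.arange(n) / fs
    wave = amp * np.sin(2 * np.pi * f * t + phase) * _taper(n, int(_EDGE_TAPER_S * fs))
    return wave[:, None] * d[None, :]


def gen_accel(t: GroundTruth, c: SynthConfig) -> RawRecording:
    """Render a ground-truth night as raw tri-axial acceleration in g."""
    rng = _rng(c, t.subject_index, 1)
    fs = c.sample_rate_hz
    n_epochs = len(t.hypnogram)
    eplen = c.epoch_length_s
    total = int(round(n_epochs * eplen * fs))
    sig = np.zeros((total, 3))
    sleep = t.hypnogram.stages != "W"
    shift_every = max(1, int(round(c.posture_shift_period_min * 60.0 / eplen)))
    orientation = _random_orientation(rng)
    wake_run = 0
    prev_sleep = True
    for e in range(n_epochs):
        lo = int(round(e * eplen * fs))
        hi = int(round((e + 1) * eplen * fs))
        n = hi - lo
        if not sleep[e]:
            # posture shift at wake-bout start and periodically within the bout
            if prev_sleep or wake_run % shift_every == 0:
                orientation = _random_orientation(rng)
            wake_run = 0 if prev_sleep else wake_run + 1
            prev_sleep = False
            # restless wrist: per-block orientation dither + movement; the
            # final block before sleep settles on the base posture so the
            # wake->sleep boundary is step-free
            next_sleep = e + 1 >= n_epochs or sleep[e + 1]
            edges = _block_edges(n, fs, _DITHER_BLOCK_S)
            for b0, b1 in zip(edges[:-1], edges[1:]):
                if next_sleep and b1 == n:
                    sig[lo + b0 : lo + b1] = orientation
                    continue
                tilt = _random_orientation(rng)
                block_orient = orientation + 0.5 * tilt
                block_orient /= np.linalg.norm(block_orient)
                sig[lo + b0 : lo + b1] = block_orient
            n_move = n - int(round(_MOVEMENT_GAP_S * fs))
            sig[lo : lo + n_move] += _oscillation(rng, n_move, fs, c.wake_movement_amplitude_g)
        else:
            prev_sleep = True
            wake_run = 0
            sig[lo:hi] = orientation
            if rng.random() < c.sleep_residual_movement_prob:
                b_lo = lo + int(round(5.0 * fs))
                b_hi = min(b_lo + int(round(_BURST_DURATION_S * fs)), hi)
                nb = b_hi - b_lo
                # disturbed-sleep burst: movement plus per-block posture wobble
                burst_edges = _block_edges(nb, fs, _DITHER_BLOCK_S)
                for b0, b1 in zip(burst_edges[:-1], burst_edges[1:]):
                    tilt = _random_orientation(rng)
                    wobble = orientation + 0.5 * tilt
                    sig[b_lo + b0 : b_lo + b1] = wobble / np.linalg.norm(wobble)
                sig[b_lo:b_hi] += _oscillation(
                    rng, nb, fs, c.wake_movement_amplitude_g
                )
    if c.sensor_noise_sd_g > 0:
        sig += rng.normal(0.0, c.sensor_noise_sd_g, sig.shape)
    return RawRecording(
        subject_id=t.subject_id,
        start_time=t.hypnogram.grid.start_time,
        sample_rate_hz=fs,
        ax=sig[:, 0], ay=sig[:, 1], az=sig[:, 2],
    )


def gen_cohort(c: SynthConfig) -> list[tuple[RawRecording, GroundTruth]]:
    """Generate ``n_subjects`` independent, reproducible nights."""
    if c.n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    out = []
    for i in range(c.n_subjects):
        truth = gen_hypnogram(c, i)
        out.append((gen_accel(truth, c), truth))
    return out


def gen_truth_cohort(c: SynthConfig) -> list[GroundTruth]:
    """Hypnograms only - cheap when raw acceleration is not needed."""
    if c.n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    return [gen_hypnogram(c, i) for i in range(c.n_subjects)]
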