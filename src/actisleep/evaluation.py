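"""Per-subject confusion statistics, sleep endpoints, cohort aggregation,
Bland-Altman agreement, and the sensitivity/specificity selection rule.

Sleep is the positive class everywhere: an epoch is TP when both PSG and the
algorithm call it sleep, TN when both call it wake. Metrics are percentages;
a metric whose denominator is zero is flagged undefined (``None``), never
silently reported as 0. The one deliberate exception is F1 when sensitivity
is zero but its own denominator is positive - then F1 is exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import SLEEP, WAKE, SleepWakeSeries
from .errors import AlignmentError, ParameterError

METRICS = ("accuracy", "sensitivity", "specificity", "precision", "f1")
ENDPOINTS = ("waso_min", "tst_min", "se_pct")


@dataclass
class ConfusionStats:
    """Epoch-level confusion counts and the derived percentage metrics."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    f1: float | None = None

    @property
    def n_epochs(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _pct(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def confusion(pred: SleepWakeSeries, truth: SleepWakeSeries) -> ConfusionStats:
    """Compare aligned equal-length prediction and PSG series epoch by epoch."""
    if len(pred) != len(truth):
        raise AlignmentError(
            f"length mismatch: prediction {len(pred)} vs truth {len(truth)} epochs"
        )
    p, t = pred.labels, truth.labels
    tp = int(np.sum((p == SLEEP) & (t == SLEEP)))
    tn = int(np.sum((p == WAKE) & (t == WAKE)))
    fp = int(np.sum((p == SLEEP) & (t == WAKE)))
    fn = int(np.sum((p == WAKE) & (t == SLEEP)))
    sens = _pct(tp, tp + fn)
    spec = _pct(tn, tn + fp)
    prec = _pct(tp, tp + fp)
    acc = _pct(tp + tn, tp + tn + fp + fn)
    if sens is None:
        f1 = None
    elif sens == 0.0:
        f1 = 0.0  # harmonic mean vanishes whenever sensitivity does
    elif prec is None:
        f1 = None  # unreachable when sens > 0, kept for safety
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return ConfusionStats(tp, tn, fp, fn, acc, sens, spec, prec, f1)


@dataclass
class SleepEndpoints:
    """WASO / TST / SE for one night; WASO and onset are None when the night
    contains no scored sleep."""

    waso_min: float | None
    tst_min: float
    se_pct: float
    onset_epoch: int | None = None
    offset_epoch: int | None = None


def endpoints(
    s: SleepWakeSeries,
    annotated_epochs: int | None = None,
    onset_consecutive_epochs: int = 1,
) -> SleepEndpoints:
    """Sleep endpoints from a binary series.

    Onset is the first epoch starting a run of ``onset_consecutive_epochs``
    sleep epochs (default 1: the first sleep epoch); offset is the last sleep
    epoch. WASO sums the wake between onset and offset, TST all scored sleep,
    and SE is sleep as a percentage of ``annotated_epochs`` (defaults to the
    series length).
    """
    if onset_consecutive_epochs < 1:
        raise ParameterError("onset_consecutive_epochs must be >= 1")
    annotated = len(s) if annotated_epochs is None else int(annotated_epochs)
    if annotated < 1:
        raise ParameterError("annotated_epochs must be >= 1")
    ep_min = s.grid.epoch_length_s / 60.0
    labels = s.labels
    sleep_idx = np.nonzero(labels == SLEEP)[0]
    tst = len(sleep_idx) * ep_min
    se = 100.0 * len(sleep_idx) / annotated
    if len(sleep_idx) == 0:
        return SleepEndpoints(None, 0.0, 0.0, None, None)
    k = onset_consecutive_epochs
    onset = None
    if k == 1:
        onset = int(sleep_idx[0])
    else:
        run = 0
        for i, v in enumerate(labels):
            run = run + 1 if v == SLEEP else 0
            if run == k:
                onset = i - k + 1
                break
    if onset is None:  # no qualifying run; fall back to first sleep epoch
        onset = int(sleep_idx[0])
    offset = int(sleep_idx[-1])
    waso = float(np.sum(labels[onset : offset + 1] == WAKE)) * ep_min
    return SleepEndpoints(waso, tst, se, onset, offset)


@dataclass
class CohortSummary:
    """Per-algorithm cohort means and SDs of the confusion metrics."""

    algorithm: str
    n_subjects: int
    mean: dict = field(default_factory=dict)      # metric -> mean over subjects
    sd: dict = field(default_factory=dict)        # metric -> population SD
    n_undefined: dict = field(default_factory=dict)
    selected: bool = False

    def formatted(self, metric: str, digits: int = 1) -> str:
        m, s = self.mean.get(metric), self.sd.get(metric)
        if m is None:
            return "undefined"
        return f"{m:.{digits}f} ({s:.{digits}f})"


def cohort_aggregate(per_subject: list[ConfusionStats], algorithm: str = "") -> CohortSummary:
    """Unweighted mean and population SD of each metric across subjects.

    Subjects with an undefined metric are excluded pairwise for that metric,
    with the exclusion count reported in ``n_undefined``.
    """
    if not per_subject:
        raise ParameterError("cohort_aggregate requires at least one subject")
    out = CohortSummary(algorithm=algorithm, n_subjects=len(per_subject))
    for metric in METRICS:
        vals = [getattr(c, metric) for c in per_subject]
        defined = [v for v in vals if v is not None]
        out.n_undefined[metric] = len(vals) - len(defined)
        if defined:
            arr = np.asarray(defined, dtype=float)
            out.mean[metric] = float(arr.mean())
            out.sd[metric] = float(arr.std(ddof=0))
        else:
            out.mean[metric] = None
            out.sd[metric] = None
    return out


@dataclass
class AgreementStats:
    """Bland-Altman agreement between algorithm and PSG endpoint values."""

    me: float
    rmse: float
    pearson_r: float | None
    loa_upper: float | None
    loa_lower: float | None
    ci_width: float | None
    n: int


def bland_altman(pred_endpoint, truth_endpoint) -> AgreementStats:
    """Agreement of paired per-subject endpoint values.

    Differences are ``pred - truth``. ME is their mean, RMSE the root mean
    square, limits of agreement ME +/- 1.96 x sample SD (ddof=1). Dispersion
    terms are undefined for n < 2; the correlation is undefined when either
    vector has zero variance.
    """
    pred = np.asarray(pred_endpoint, dtype=float)
    truth = np.asarray(truth_endpoint, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1 or len(pred) == 0:
        raise ParameterError("paired non-empty equal-length vectors required")
    d = pred - truth
    me = float(d.mean())
    rmse = float(np.sqrt(np.mean(d**2)))
    n = len(d)
    if n < 2:
        return AgreementStats(me, rmse, None, None, None, None, n)
    sd = float(d.std(ddof=1))
    loa_up, loa_lo = me + 1.96 * sd, me - 1.96 * sd
    if pred.std() == 0 or truth.std() == 0:
        r = None
    else:
        r = float(sps.pearsonr(pred, truth).statistic)
    return AgreementStats(me, rmse, r, loa_up, loa_lo, loa_up - loa_lo, n)


def select_algorithms(
    summaries: list[CohortSummary], sens_min: float = 75.0, spec_min: float = 45.0
) -> list[CohortSummary]:
    """Keep algorithms whose cohort-mean sensitivity and specificity pass the
    minimum levels; sets the ``selected`` flag in place on every summary."""
    selected = []
    for s in summaries:
        sens, spec = s.mean.get("sensitivity"), s.mean.get("specificity")
        s.selected = (
            sens is not None and spec is not None
            and sens >= sens_min and spec >= spec_min
        )
        if s.selected:
            selected.append(s)
    return selected
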