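"""Webster rescoring rules for actigraphy sleep-wake output.

Actigraphy under-detects wake; the classic remedy is a set of heuristic
rules that convert sleep epochs to wake based on the length of surrounding
wake runs (Webster et al. 1982). Only sleep -> wake changes are possible,
so total scored sleep is non-increasing under any rule subset; against a
fixed reference this can only lower sensitivity and raise specificity.

Durations are in minutes and converted to 30-s epochs as minutes x 2. Rules
are applied sequentially in their listed order, each on the output of the
previous one, so later rules see earlier rescorings (cascade semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SLEEP, WAKE, SleepWakeSeries
from .errors import ParameterError


@dataclass(frozen=True)
class AfterWakeRule:
    """After >= ``min_wake_min`` of wake, rescore the immediately following
    sleep epochs (up to ``rescore_sleep_min``) as wake."""

    min_wake_min: float
    rescore_sleep_min: float

    def __post_init__(self):
        if self.min_wake_min <= 0 or self.rescore_sleep_min <= 0:
            raise ParameterError("rule durations must be positive")


@dataclass(frozen=True)
class SurroundedRule:
    """Sleep bouts <= ``max_sleep_min`` flanked by >= ``min_flank_wake_min``
    of wake on both sides are rescored entirely as wake."""

    max_sleep_min: float
    min_flank_wake_min: float

    def __post_init__(self):
        if self.max_sleep_min <= 0 or self.min_flank_wake_min <= 0:
            raise ParameterError("rule durations must be positive")


@dataclass
class RescoreRuleSet:
    """Ordered Webster rule list; the default is the canonical a-e set."""

    rules: list = field(
        default_factory=lambda: [
            AfterWakeRule(4, 1),       # a
            AfterWakeRule(10, 3),      # b
            AfterWakeRule(15, 4),      # c
            SurroundedRule(6, 10),     # d
            SurroundedRule(10, 20),    # e
        ]
    )
    enabled: list[bool] | None = None

    def active_rules(self) -> list:
        if self.enabled is None:
            return list(self.rules)
        if len(self.enabled) != len(self.rules):
            raise ParameterError("enabled flags must match the rule list")
        return [r for r, on in zip(self.rules, self.enabled) if on]


def _runs(labels: np.ndarray):
    """Yield (value, start, stop) for maximal constant runs (stop exclusive)."""
    n = len(labels)
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            yield int(labels[start]), start, i
            start = i


def _apply_after_wake(labels: np.ndarray, rule: AfterWakeRule, eplen_s: int) -> np.ndarray:
    per_min = 60 // eplen_s
    need = int(round(rule.min_wake_min * per_min))
    limit = int(round(rule.rescore_sleep_min * per_min))
    out = labels.copy()
    runs = list(_runs(out))
    for k, (val, start, stop) in enumerate(runs):
        if val == WAKE and stop - start >= need and k + 1 < len(runs):
            nval, nstart, nstop = runs[k + 1]
            if nval == SLEEP:
                out[nstart : min(nstop, nstart + limit)] = WAKE
    return out


def _apply_surrounded(labels: np.ndarray, rule: SurroundedRule, eplen_s: int) -> np.ndarray:
    per_min = 60 // eplen_s
    max_sleep = int(round(rule.max_sleep_min * per_min))
    min_flank = int(round(rule.min_flank_wake_min * per_min))
    out = labels.copy()
    runs = list(_runs(out))
    for k, (val, start, stop) in enumerate(runs):
        if val != SLEEP or stop - start > max_sleep:
            continue
        if k == 0 or k == len(runs) - 1:
            continue  # bouts at the record edge have no flank on one side
        pval, pstart, pstop = runs[k - 1]
        nval, nstart, nstop = runs[k + 1]
        if (pstop - pstart >= min_flank) and (nstop - nstart >= min_flank):
            out[start:stop] = WAKE
    return out


def webster_rescore(s: SleepWakeSeries, r: RescoreRuleSet | None = None) -> SleepWakeSeries:
    """Apply the Webster rescoring rules to a binary sleep/wake series."""
    r = r or RescoreRuleSet()
    eplen = s.grid.epoch_length_s
    if 60 % eplen:
        raise ParameterError("epoch length must divide one minute")
    labels = s.labels.copy()
    for rule in r.active_rules():
        if isinstance(rule, AfterWakeRule):
            labels = _apply_after_wake(labels, rule, eplen)
        elif isinstance(rule, SurroundedRule):
            labels = _apply_surrounded(labels, rule, eplen)
        else:
            raise ParameterError(f"unknown rescore rule {rule!r}")
    return SleepWakeSeries(s.grid, labels, source=f"{s.source}_rescored")
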