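"""Dosing event model and compilation to piecewise-constant schedules."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["DoseEvent", "CompiledSchedule", "compile_events"]

DRUGS = ("propofol", "fentanyl")
KINDS = ("infusion_stop", "clamp_stop", "bolus", "infusion_start", "clamp_start")
#: Earliest legal event time: the pre-induction fentanyl bolus at -5 min.
EARLIEST_TIME = -5.0


@dataclass(frozen=True)
class DoseEvent:
    """A dosing event: bolus, infusion rate change or concentration clamp.

    Amounts are mg for propofol and µg for fentanyl; rates are amount/min;
    clamp targets are mg/L (propofol) or ng/mL (fentanyl).
    """

    time: float
    drug: str
    kind: str
    amount: float | None = None
    rate: float | None = None
    target: float | None = None

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.time < EARLIEST_TIME:
            raise ValueError(f"event time {self.time} precedes {EARLIEST_TIME} min")
        if self.kind == "bolus":
            if self.amount is None or self.amount < 0:
                raise ValueError("bolus requires amount >= 0")
            if self.rate is not None or self.target is not None:
                raise ValueError("bolus carries only an amount")
        elif self.kind == "infusion_start":
            if self.rate is None or self.rate < 0:
                raise ValueError("infusion_start requires rate >= 0")
            if self.amount is not None or self.target is not None:
                raise ValueError("infusion_start carries only a rate")
        elif self.kind == "clamp_start":
            if self.target is None or self.target <= 0:
                raise ValueError("clamp_start requires target > 0")
            if self.amount is not None or self.rate is not None:
                raise ValueError("clamp_start carries only a target")
        else:  # stops carry nothing
            if self.amount is not None or self.rate is not None or self.target is not None:
                raise ValueError(f"{self.kind} carries no amount/rate/target")

    @property
    def sort_key(self):
        return (self.time, KINDS.index(self.kind))


@dataclass
class CompiledSchedule:
    """Per-drug piecewise-constant schedule derived from a sorted event list.

    ``breaks`` are the distinct event times; on the half-open interval
    ``[breaks[k], breaks[k+1])`` the infusion rate is ``rates[drug][k]`` and
    the clamp target (or nan if unclamped) is ``clamp[drug][k]``.  Boluses
    are keyed by break index.
    """

    breaks: np.ndarray
    rates: dict[str, np.ndarray]
    clamp: dict[str, np.ndarray]
    boluses: dict[str, np.ndarray]

    def rate_at(self, drug: str, t: float) -> float:
        k = int(np.searchsorted(self.breaks, t, side="right")) - 1
        if k < 0:
            return 0.0
        return float(self.rates[drug][min(k, len(self.rates[drug]) - 1)])


def compile_events(events: Iterable[DoseEvent]) -> CompiledSchedule:
    """Sort/validate events and compile per-drug rate/clamp step functions."""
    evs: Sequence[DoseEvent] = sorted(events, key=lambda e: e.sort_key)
    times = sorted({e.time for e in evs})
    breaks = np.asarray(times, dtype=float)
    n = max(len(breaks), 1)
    rates = {d: np.zeros(n) for d in DRUGS}
    clamp = {d: np.full(n, np.nan) for d in DRUGS}
    boluses = {d: np.zeros(n) for d in DRUGS}
    cur_rate = {d: 0.0 for d in DRUGS}
    cur_clamp = {d: np.nan for d in DRUGS}
    idx = {t: i for i, t in enumerate(times)}
    for e in evs:
        i = idx[e.time]
        if e.kind == "bolus":
            boluses[e.drug][i] += e.amount
        elif e.kind == "infusion_start":
            cur_rate[e.drug] = e.rate
        elif e.kind == "infusion_stop":
            cur_rate[e.drug] = 0.0
        elif e.kind == "clamp_start":
            cur_clamp[e.drug] = e.target
        elif e.kind == "clamp_stop":
            cur_clamp[e.drug] = np.nan
        rates[e.drug][i:] = cur_rate[e.drug]
        clamp[e.drug][i:] = cur_clamp[e.drug]
    for d in DRUGS:
        clamped = ~np.isnan(clamp[d])
        if np.any((boluses[d] > 0) & clamped):
            raise ValueError(f"bolus of {d} while its plasma concentration is clamped")
    return CompiledSchedule(breaks=breaks, rates=rates, clamp=clamp, boluses=boluses)
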