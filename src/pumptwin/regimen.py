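"""Daily insulin totals and basal/bolus infusion schedules.

The total daily requirement for an insulin-naive patient follows the
weight-and-fasting-glucose rule of thumb

    U_total = 6 * K * (P - 100) / 2000

with K the body weight in kg, P the fasting glucose in mg/dL and 100 the
normal-glucose reference.  The daily total is then split into a basal
fraction delivered as frequent micro-doses inside fixed time windows
(e.g. 0.1 U every 6 min) and a bolus fraction delivered as a few large
pre-meal doses.  Clock arithmetic wraps at midnight so windows like
20:00-01:00 are valid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "PatientProfile",
    "TimeWindow",
    "RegimenSegment",
    "DailyRegimen",
    "daily_insulin_requirement",
    "build_regimen",
    "reference_regimen",
    "write_regimen_csv",
]

MINUTES_PER_DAY = 24 * 60


@dataclass(frozen=True)
class PatientProfile:
    """Patient weight (kg) and fasting blood glucose (mg/dL)."""

    weight: float
    fasting_glucose: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"weight must be > 0 kg, got {self.weight}")
        if self.fasting_glucose < 100:
            raise ValueError(
                "fasting_glucose below the 100 mg/dL reference yields a "
                f"non-positive insulin dose (got {self.fasting_glucose})"
            )


def _parse_clock(t: "str | int | float") -> int:
    """Clock time -> minutes since midnight. Accepts 'HH:MM' or minutes."""
    if isinstance(t, str):
        hh, mm = t.split(":")
        minutes = int(hh) * 60 + int(mm)
    else:
        minutes = int(t)
    return minutes % MINUTES_PER_DAY


def _format_clock(minutes: float) -> str:
    m = int(round(minutes)) % MINUTES_PER_DAY
    return f"{m // 60:02d}:{m % 60:02d}"


@dataclass(frozen=True)
class TimeWindow:
    """Half-open clock window [start, end), wrapping at midnight."""

    start: int  # minutes since midnight
    end: int

    @classmethod
    def parse(cls, start, end) -> "TimeWindow":
        return cls(_parse_clock(start), _parse_clock(end))

    @property
    def duration(self) -> int:
        """Window length in minutes (midnight wrap handled)."""
        d = (self.end - self.start) % MINUTES_PER_DAY
        return d if d > 0 else MINUTES_PER_DAY


@dataclass(frozen=True)
class RegimenSegment:
    """One basal window or one bolus delivery inside a daily regimen."""

    window: TimeWindow
    mode: str  # "basal" | "bolus"
    total_dose: float  # U
    per_event_dose: float  # U
    event_interval: float  # minutes between event starts

    def __post_init__(self) -> None:
        if self.mode not in ("basal", "bolus"):
            raise ValueError(f"mode must be 'basal' or 'bolus', got {self.mode!r}")
        if self.total_dose <= 0:
            raise ValueError("total_dose must be > 0")

    @property
    def n_events(self) -> int:
        n = self.total_dose / self.per_event_dose
        n_int = round(n)
        if abs(n - n_int) > 1e-9:
            raise ValueError(
                f"per_event_dose {self.per_event_dose} does not divide "
                f"segment dose {self.total_dose}"
            )
        return int(n_int)

    def event_times(self) -> list[int]:
        """Clock minute of each delivery event, wrapping at midnight."""
        return [
            int((self.window.start + k * self.event_interval) % MINUTES_PER_DAY)
            for k in range(self.n_events)
        ]


@dataclass(frozen=True)
class DailyRegimen:
    segments: tuple[RegimenSegment, ...]
    basal_fraction: float

    @property
    def total_dose(self) -> float:
        return sum(s.total_dose for s in self.segments)

    def to_frame(self) -> pd.DataFrame:
        """Flat event table: event_index, clock_time, mode, dose_U."""
        rows = []
        for seg in self.segments:
            for t in seg.event_times():
                rows.append((t, seg.mode, seg.per_event_dose))
        # order by clock time relative to the first segment's start
        anchor = self.segments[0].window.start if self.segments else 0
        rows.sort(key=lambda r: (r[0] - anchor) % MINUTES_PER_DAY)
        return pd.DataFrame(
            {
                "event_index": range(len(rows)),
                "clock_time": [_format_clock(t) for t, _, _ in rows],
                "mode": [m for _, m, _ in rows],
                "dose_U": [d for _, _, d in rows],
            }
        )


def daily_insulin_requirement(profile: PatientProfile) -> float:
    """Total daily insulin in units: 6*K*(P-100)/2000."""
    return 6.0 * profile.weight * (profile.fasting_glucose - 100.0) / 2000.0


def build_regimen(
    total: float,
    basal_fraction: float,
    bolus_count: int,
    basal_windows: Sequence[TimeWindow],
    basal_interval: float,
    *,
    bolus_windows: Sequence[TimeWindow] | None = None,
    bolus_event_dose: float | None = None,
) -> DailyRegimen:
    """Split a daily total into equal boluses plus equal basal windows.

    The bolus share ``total * (1 - basal_fraction)`` is divided equally
    over ``bolus_count`` deliveries; the basal share is divided equally
    over ``basal_windows``, each delivered as micro-doses every
    ``basal_interval`` minutes.  ``bolus_event_dose`` optionally breaks
    each bolus into repeated equal sub-doses (e.g. a 4 U meal bolus as
    2 U events); by default the bolus is one event.
    """
    if not 0.0 < basal_fraction < 1.0:
        raise ValueError(f"basal_fraction must be in (0, 1), got {basal_fraction}")
    if bolus_count < 1:
        raise ValueError("bolus_count must be >= 1")
    if len(basal_windows) == 0:
        raise ValueError("at least one basal window is required")
    if basal_interval <= 0:
        raise ValueError("basal_interval must be > 0 minutes")

    basal_total = total * basal_fraction
    bolus_total = total - basal_total
    per_bolus = bolus_total / bolus_count
    per_window = basal_total / len(basal_windows)

    segments: list[RegimenSegment] = []

    if bolus_windows is None:
        # evenly spaced nominal slots starting at 06:00
        bolus_windows = [
            TimeWindow.parse(6 * 60 + k * (MINUTES_PER_DAY // bolus_count), 0)
            for k in range(bolus_count)
        ]
        bolus_windows = [TimeWindow(w.start, (w.start + 60) % MINUTES_PER_DAY) for w in bolus_windows]
    if len(bolus_windows) != bolus_count:
        raise ValueError("bolus_windows length must equal bolus_count")

    for w in bolus_windows:
        event_dose = bolus_event_dose if bolus_event_dose is not None else per_bolus
        n_sub = per_bolus / event_dose
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError(
                f"bolus_event_dose {event_dose} does not divide the per-meal bolus {per_bolus}"
            )
        n_sub = int(round(n_sub))
        interval = w.duration / n_sub
        segments.append(
            RegimenSegment(
                window=w, mode="bolus", total_dose=per_bolus,
                per_event_dose=event_dose, event_interval=interval,
            )
        )

    for w in basal_windows:
        n_events = w.duration / basal_interval
        if abs(n_events - round(n_events)) > 1e-9:
            raise ValueError(
                f"basal window of {w.duration} min is not divisible by the "
                f"{basal_interval} min interval"
            )
        n_events = int(round(n_events))
        segments.append(
            RegimenSegment(
                window=w, mode="basal", total_dose=per_window,
                per_event_dose=per_window / n_events, event_interval=basal_interval,
            )
        )

    segments.sort(key=lambda s: s.window.start)
    regimen = DailyRegimen(segments=tuple(segments), basal_fraction=basal_fraction)
    if abs(regimen.total_dose - total) > 1e-9:
        raise AssertionError("dose conservation violated in build_regimen")
    return regimen


def reference_regimen(total: float = 27.0) -> DailyRegimen:
    """The shipped reference schedule: three 4 U meal boluses (as 2 U
    events) in 2 h pre-meal windows and three 5 U basal windows at
    0.1 U per 6 min, summing to 27 U/day.

    Note the basal share here is 15/27 ~ 55.6%; a 40% basal preset is
    obtained by calling :func:`build_regimen` with ``basal_fraction=0.4``.
    """
    scale = total / 27.0
    bolus_windows = [
        TimeWindow.parse("4:00", "6:00"),
        TimeWindow.parse("11:00", "13:00"),
        TimeWindow.parse("18:00", "20:00"),
    ]
    basal_windows = [
        TimeWindow.parse("6:00", "11:00"),
        TimeWindow.parse("13:00", "18:00"),
        TimeWindow.parse("20:00", "1:00"),  # wraps midnight
    ]
    return build_regimen(
        total=total,
        basal_fraction=15.0 / 27.0,
        bolus_count=3,
        basal_windows=basal_windows,
        basal_interval=6.0,
        bolus_windows=bolus_windows,
        bolus_event_dose=2.0 * scale,
    )


def write_regimen_csv(regimen: DailyRegimen, path) -> None:
    regimen.to_frame().to_csv(path, index=False)
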