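"""Core domain model for glucose/heart-rate time series and detected episodes.

The model mirrors the data a flash-glucose-monitoring (FGM) sensor and a
wrist-worn activity tracker jointly produce for one patient:

* :class:`Sample` — one timestamped scalar on a named channel (blood glucose
  in mg/dL on a nominal 15-minute grid, or heart rate in bpm on a nominal
  1-minute grid).
* :class:`EventRecord` — one row of an FGM reader export (automatic or
  scanned glucose reading, insulin bolus, meal, free-text health note).
* :class:`IntervalAnnotation` — a tracked sleep or workout session.
* :class:`PatientProfile` — the patient's declared weekday habit schedule
  plus the four clinician-personalised alert thresholds.
* :class:`Episode` — one detected pattern occurrence.
* :class:`PatternSpec` — the declarative parameters of one detector.

All timestamps are naive local clock times at minute resolution; the
patient's day is analysed in local time and no timezone arithmetic is done.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Channel(str, Enum):
    BG = "BG"
    HR = "HR"


#: Nominal sampling period per channel, in minutes. The FGM sensor stores one
#: glucose value every 15 minutes; the tracker reports one heart-rate value
#: per minute.
NOMINAL_PERIOD_MIN: dict[Channel, int] = {Channel.BG: 15, Channel.HR: 1}


class AcquisitionMode(str, Enum):
    AUTO = "auto"
    SCAN = "scan"
    NA = "n/a"


@dataclass(frozen=True)
class Sample:
    """One timestamped measurement on a channel.

    ``mode`` distinguishes automatically logged glucose values from values the
    patient obtained by scanning the sensor; it is ``n/a`` for heart rate.
    """

    timestamp: dt.datetime
    channel: Channel
    value: float
    mode: AcquisitionMode = AcquisitionMode.NA

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"sample value must be > 0, got {self.value}")
        if self.mode is AcquisitionMode.SCAN and self.channel is not Channel.BG:
            raise ValueError("mode=scan is only valid for the BG channel")


class EventKind(str, Enum):
    BG_AUTO = "bg_auto"
    BG_SCAN = "bg_scan"
    INSULIN = "insulin"
    MEAL = "meal"
    HEALTH_NOTE = "health_note"


#: Event kinds whose ``value`` attribute is mandatory.
_VALUED_KINDS = {EventKind.BG_AUTO, EventKind.BG_SCAN, EventKind.INSULIN}


@dataclass(frozen=True)
class EventRecord:
    """One row of the FGM reader export: a timestamped event of one kind."""

    timestamp: dt.datetime
    kind: EventKind
    value: Optional[float] = None
    note: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind in _VALUED_KINDS:
            if self.value is None or self.value <= 0:
                raise ValueError(f"{self.kind.value} event requires value > 0")
        if self.kind is EventKind.HEALTH_NOTE and not self.note:
            raise ValueError("health_note event requires a note")

    def to_sample(self) -> Sample:
        """Convert a glucose event into a BG :class:`Sample`."""
        if self.kind is EventKind.BG_AUTO:
            return Sample(self.timestamp, Channel.BG, float(self.value), AcquisitionMode.AUTO)
        if self.kind is EventKind.BG_SCAN:
            return Sample(self.timestamp, Channel.BG, float(self.value), AcquisitionMode.SCAN)
        raise ValueError(f"event of kind {self.kind.value} carries no sample")


class IntervalKind(str, Enum):
    SLEEP = "sleep"
    WORKOUT = "workout"


@dataclass(frozen=True)
class IntervalAnnotation:
    """A tracked sleep or workout session.

    Sleep sessions may carry the minutes the subject was awake in bed and the
    minutes of restless sleep; workouts may carry an ordinal intensity.
    """

    start: dt.datetime
    end: dt.datetime
    kind: IntervalKind
    intensity: Optional[int] = None
    minutes_awake: Optional[float] = None
    minutes_restless: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval start {self.start} must precede end {self.end}")
        length = self.duration_min
        for name in ("minutes_awake", "minutes_restless"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= length):
                raise ValueError(f"{name}={v} outside [0, {length}] for a {length}-min interval")

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0

    def contains(self, t: dt.datetime) -> bool:
        """Half-open membership test: ``start <= t < end``."""
        return self.start <= t < self.end


WEEKDAYS = (
    "monday", "tuesday", "wednesday", "thursday", "friday", "saturday", "sunday",
)


@dataclass(frozen=True)
class DaySchedule:
    """Habit schedule for one weekday: meal clock times, bedtime, wake time."""

    breakfast: dt.time
    lunch: dt.time
    dinner: dt.time
    bedtime: dt.time
    wake: dt.time
    snacks: tuple[dt.time, ...] = ()

    def __post_init__(self) -> None:
        if not (self.breakfast < self.lunch < self.dinner):
            raise ValueError("meal times must satisfy breakfast < lunch < dinner")


@dataclass(frozen=True)
class Thresholds:
    """Patient-specific alert thresholds, set by the clinician."""

    hypo_mgdl: float
    hyper_mgdl: float
    brady_bpm: float
    tachy_bpm: float

    def violations(self) -> list[str]:
        out = []
        for name in ("hypo_mgdl", "hyper_mgdl", "brady_bpm", "tachy_bpm"):
            if getattr(self, name) <= 0:
                out.append(f"{name} must be positive")
        if self.hypo_mgdl >= self.hyper_mgdl:
            out.append("hypo_mgdl < hyper_mgdl violated")
        if self.brady_bpm >= self.tachy_bpm:
            out.append("brady_bpm < tachy_bpm violated")
        return out


class ProfileValidationError(ValueError):
    """Raised with the full list of profile violations."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


@dataclass(frozen=True)
class PatientProfile:
    """Weekday habit schedule plus the four alert thresholds.

    ``schedule`` maps weekday index (0=Monday .. 6=Sunday) to the day's
    :class:`DaySchedule`; all seven entries must be present.
    """

    patient_id: str
    schedule: dict[int, DaySchedule]
    thresholds: Thresholds

    def __post_init__(self) -> None:
        violations = []
        for i, name in enumerate(WEEKDAYS):
            if i not in self.schedule:
                violations.append(f"schedule missing {name}")
        violations.extend(self.thresholds.violations())
        if violations:
            raise ProfileValidationError(violations)

    def schedule_for(self, day: dt.date) -> DaySchedule:
        return self.schedule[day.weekday()]


@dataclass(frozen=True)
class Episode:
    """One detected pattern occurrence.

    ``start``/``end`` are the timestamps of the first and last contributing
    samples (for complex patterns, of the first and last component).
    ``duration_min`` follows the per-type convention of the detection engine:
    state episodes add one nominal sampling period to the span, trend and
    complex episodes use the pure span.
    """

    patient_id: str
    pattern: str
    start: dt.datetime
    end: dt.datetime
    n_samples: int
    duration_min: float
    channel: Optional[Channel] = None
    context_tag: Optional[str] = None
    components: tuple["Episode", ...] = ()
    details: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("episode start must not be after end")
        if self.n_samples < 1:
            raise ValueError("episode must contain at least one sample")

    @property
    def span_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


class PatternType(str, Enum):
    STATE = "state"
    TREND = "trend"
    COMPLEX = "complex"


class Direction(str, Enum):
    INCREASING = "increasing"
    DECREASING = "decreasing"


class Relation(str, Enum):
    PRECEDES = "PRECEDES"
    DURING = "DURING"


@dataclass(frozen=True)
class PatternSpec:
    """Declarative parameters of one detector.

    Which optional fields are required depends on ``type``: state patterns
    need ``comparator`` and ``threshold``, trend patterns need ``direction``,
    ``min_rate`` and ``min_duration``, complex patterns need ``relation``.
    ``min_rate`` is expressed in mg/dL per 15 min regardless of the actual
    sample spacing.
    """

    name: str
    type: PatternType
    channel: Optional[Channel] = None
    comparator: Optional[str] = None  # "<" or ">"
    threshold: Optional[float] = None
    direction: Optional[Direction] = None
    min_rate: Optional[float] = None
    min_duration: Optional[float] = None
    relation: Optional[Relation] = None
    max_gap: Optional[float] = None
    context: Optional[str] = None  # "sleep" | "workout" | "night" | None

    def __post_init__(self) -> None:
        if self.type is PatternType.STATE:
            if self.comparator not in ("<", ">") or self.threshold is None:
                raise ValueError(f"state pattern {self.name!r} needs comparator and threshold")
            if self.threshold <= 0:
                raise ValueError("threshold must be > 0")
        elif self.type is PatternType.TREND:
            if self.direction is None or self.min_rate is None or self.min_duration is None:
                raise ValueError(f"trend pattern {self.name!r} needs direction, min_rate, min_duration")
            if self.min_rate <= 0:
                raise ValueError("min_rate must be > 0")
        elif self.type is PatternType.COMPLEX:
            if self.relation is None:
                raise ValueError(f"complex pattern {self.name!r} needs a temporal relation")
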