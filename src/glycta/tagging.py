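"""Contextual tagging of BG and HR samples within the patient's day.

Every sample receives two context labels:

* the **profile tag**, derived purely from the patient's declared habit
  schedule — one of ``awakening``, ``after_breakfast``, ``before_lunch``,
  ``after_lunch``, ``before_dinner``, ``after_dinner``, ``night``;
* the **Fitbit tag**, derived from tracker data — ``sleep``, ``workout``,
  ``routine``, or ``NA`` when the tracker was not worn. The tracker is
  considered not worn at time t if no HR sample exists in the closed window
  [t − 5 min, t + 5 min].

The profile-tag day partition is a declared convention built only from the
schedule times the intake form collects: with breakfast B, lunch L, dinner D,
bedtime and wake time,

    night            = [bedtime, wake)            (may cross midnight)
    awakening        = [wake, B)
    after_breakfast  = [B, midpoint(B, L))
    before_lunch     = [midpoint(B, L), L)
    after_lunch      = [L, midpoint(L, D))
    before_dinner    = [midpoint(L, D), D)
    after_dinner     = [D, bedtime)

All windows are half-open on the right; midnight-crossing nights use the
bedtime weekday's schedule for the whole night. The partition is total: any
non-night minute before breakfast falls in ``awakening`` and any non-night
minute after dinner falls in ``after_dinner``, so schedules that differ
between adjacent weekdays cannot leave a minute untagged.
"""

from __future__ import annotations

import datetime as dt
from bisect import bisect_left
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .model import (
    DaySchedule,
    IntervalAnnotation,
    IntervalKind,
    PatientProfile,
    Sample,
)

#: Half-width of the tracker-not-worn window, minutes (closed on both ends).
NA_WINDOW_MIN = 5


class ProfileTag(str, Enum):
    AWAKENING = "awakening"
    AFTER_BREAKFAST = "after_breakfast"
    BEFORE_LUNCH = "before_lunch"
    AFTER_LUNCH = "after_lunch"
    BEFORE_DINNER = "before_dinner"
    AFTER_DINNER = "after_dinner"
    NIGHT = "night"


class FitbitTag(str, Enum):
    SLEEP = "sleep"
    WORKOUT = "workout"
    ROUTINE = "routine"
    NA = "NA"


class TagPreference(str, Enum):
    FITBIT_FIRST = "fitbit_first"
    PROFILE_ONLY = "profile_only"


@dataclass(frozen=True)
class TaggedSample:
    sample: Sample
    profile_tag: ProfileTag
    fitbit_tag: FitbitTag


def night_span(day: dt.date, sched: DaySchedule) -> tuple[dt.datetime, dt.datetime]:
    """Night interval anchored at ``day``'s bedtime, per that day's schedule.

    If bedtime is later than wake time the night crosses midnight and ends at
    the same schedule's wake time on the following day.
    """
    start = dt.datetime.combine(day, sched.bedtime)
    if sched.bedtime > sched.wake:
        end = dt.datetime.combine(day + dt.timedelta(days=1), sched.wake)
    else:
        end = dt.datetime.combine(day, sched.wake)
    return start, end


def schedule_night_spans(
    profile: PatientProfile, first_day: dt.date, last_day: dt.date
) -> list[IntervalAnnotation]:
    """Schedule-derived night intervals, one per bedtime in [first, last]."""
    out = []
    day = first_day
    while day <= last_day:
        start, end = night_span(day, profile.schedule_for(day))
        if start < end:
            out.append(IntervalAnnotation(start=start, end=end, kind=IntervalKind.SLEEP))
        day += dt.timedelta(days=1)
    return out


def _minutes(t: dt.time) -> int:
    return t.hour * 60 + t.minute


def _midpoint(a: dt.time, b: dt.time) -> dt.time:
    m = (_minutes(a) + _minutes(b)) // 2
    return dt.time(m // 60, m % 60)


def profile_tag(t: dt.datetime, profile: PatientProfile) -> ProfileTag:
    """Profile tag of instant ``t`` under the day partition described above."""
    # night owned by the bedtime's weekday: check tonight's and yesterday's span
    for day in (t.date() - dt.timedelta(days=1), t.date()):
        start, end = night_span(day, profile.schedule_for(day))
        if start <= t < end:
            return ProfileTag.NIGHT
    s = profile.schedule_for(t.date())
    tt = t.time()
    if tt < s.breakfast:
        return ProfileTag.AWAKENING
    if tt < _midpoint(s.breakfast, s.lunch):
        return ProfileTag.AFTER_BREAKFAST
    if tt < s.lunch:
        return ProfileTag.BEFORE_LUNCH
    if tt < _midpoint(s.lunch, s.dinner):
        return ProfileTag.AFTER_LUNCH
    if tt < s.dinner:
        return ProfileTag.BEFORE_DINNER
    return ProfileTag.AFTER_DINNER


def _has_hr_near(t: dt.datetime, hr_times: Sequence[dt.datetime]) -> bool:
    lo = t - dt.timedelta(minutes=NA_WINDOW_MIN)
    hi = t + dt.timedelta(minutes=NA_WINDOW_MIN)
    i = bisect_left(hr_times, lo)
    return i < len(hr_times) and hr_times[i] <= hi


def fitbit_tag(
    t: dt.datetime,
    sleeps: Iterable[IntervalAnnotation],
    workouts: Iterable[IntervalAnnotation],
    hr: Sequence[Sample],
    _hr_times: Optional[Sequence[dt.datetime]] = None,
) -> FitbitTag:
    """Tracker-derived tag of instant ``t``.

    ``NA`` when no HR sample lies in the closed window [t−5 min, t+5 min];
    otherwise ``sleep`` if t falls in a tracked sleep session, ``workout`` if
    in a tracked workout, else ``routine``. Sleep wins over a workout
    erroneously recorded inside a sleep session.
    """
    hr_times = _hr_times if _hr_times is not None else [s.timestamp for s in hr]
    if not _has_hr_near(t, hr_times):
        return FitbitTag.NA
    if any(iv.contains(t) for iv in sleeps):
        return FitbitTag.SLEEP
    if any(iv.contains(t) for iv in workouts):
        return FitbitTag.WORKOUT
    return FitbitTag.ROUTINE


def tag_series(
    samples: Sequence[Sample],
    profile: PatientProfile,
    sleeps: Sequence[IntervalAnnotation] = (),
    workouts: Sequence[IntervalAnnotation] = (),
    hr: Optional[Sequence[Sample]] = None,
) -> list[TaggedSample]:
    """Tag every sample (BG and HR alike) with both context labels.

    ``hr`` is the HR series used for the tracker-worn test; when omitted, the
    HR samples present in ``samples`` are used. With no tracker data at all
    every Fitbit tag is ``NA`` while profile tags are still assigned.
    """
    from .model import Channel

    if hr is None:
        hr = [s for s in samples if s.channel is Channel.HR]
    hr_times = sorted(s.timestamp for s in hr)
    sleeps = sorted(sleeps, key=lambda iv: iv.start)
    workouts = sorted(workouts, key=lambda iv: iv.start)
    out = []
    for s in samples:
        out.append(
            TaggedSample(
                sample=s,
                profile_tag=profile_tag(s.timestamp, profile),
                fitbit_tag=fitbit_tag(s.timestamp, sleeps, workouts, hr, _hr_times=hr_times),
            )
        )
    return out


def effective_tag(ts: TaggedSample, preference: TagPreference = TagPreference.FITBIT_FIRST) -> str:
    """Resolve the two tags into the single context label used for analysis.

    ``fitbit_first`` returns the Fitbit tag unless it is ``NA``, in which
    case the profile tag is used; ``profile_only`` always returns the profile
    tag.
    """
    if preference is TagPreference.PROFILE_ONLY:
        return ts.profile_tag.value
    if ts.fitbit_tag is FitbitTag.NA:
        return ts.profile_tag.value
    return ts.fitbit_tag.value
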