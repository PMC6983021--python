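import datetime as dt

import pytest

from glycta.model import (
    AcquisitionMode,
    Channel,
    DaySchedule,
    IntervalAnnotation,
    IntervalKind,
    PatientProfile,
    Sample,
    Thresholds,
)

#: A Monday, so weekday arithmetic is easy to reason about.
T0 = dt.datetime(2020, 3, 2)

STANDARD_SCHEDULE = DaySchedule(
    breakfast=dt.time(7, 30),
    lunch=dt.time(12, 30),
    dinner=dt.time(19, 30),
    bedtime=dt.time(23, 0),
    wake=dt.time(7, 0),
    snacks=(dt.time(16, 30),),
)


def make_profile(bedtime=dt.time(23, 0), wake=dt.time(7, 0), **thr) -> PatientProfile:
    sched = DaySchedule(
        breakfast=STANDARD_SCHEDULE.breakfast,
        lunch=STANDARD_SCHEDULE.lunch,
        dinner=STANDARD_SCHEDULE.dinner,
        bedtime=bedtime,
        wake=wake,
        snacks=STANDARD_SCHEDULE.snacks,
    )
    thresholds = Thresholds(
        hypo_mgdl=thr.get("hypo", 70.0),
        hyper_mgdl=thr.get("hyper", 180.0),
        brady_bpm=thr.get("brady", 50.0),
        tachy_bpm=thr.get("tachy", 120.0),
    )
    return PatientProfile("t01", {i: sched for i in range(7)}, thresholds)


@pytest.fixture
def profile() -> PatientProfile:
    return make_profile()


def bg_series(values, start=T0, step_min=15) -> list[Sample]:
    """BG samples at regular spacing; None values leave holes in the grid."""
    return [
        Sample(start + dt.timedelta(minutes=i * step_min), Channel.BG, float(v), AcquisitionMode.AUTO)
        for i, v in enumerate(values)
        if v is not None
    ]


def hr_series(values, start=T0, step_min=1) -> list[Sample]:
    return [
        Sample(start + dt.timedelta(minutes=i * step_min), Channel.HR, float(v))
        for i, v in enumerate(values)
        if v is not None
    ]


def sleep(start: dt.datetime, end: dt.datetime, **kw) -> IntervalAnnotation:
    return IntervalAnnotation(start=start, end=end, kind=IntervalKind.SLEEP, **kw)


def workout(start: dt.datetime, end: dt.datetime, **kw) -> IntervalAnnotation:
    return IntervalAnnotation(start=start, end=end, kind=IntervalKind.WORKOUT, **kw)
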