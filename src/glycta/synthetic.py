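"""Seed-reproducible synthetic patients with a ground-truth pattern manifest.

The generator emulates the two data sources the analysis pipeline ingests —
an FGM sensor writing one BG value every 15 minutes and a wrist tracker
writing one HR value per minute plus sleep/workout sessions — and injects
known occurrences of every detectable pattern, so the whole pipeline can be
tested without any real patient data.

Generative model:

* BG baseline is a mean-reverting AR(1) process on the 15-minute grid
  (stationary mean ``bg_mean``, stationary s.d. ``bg_sd``, lag-1
  autocorrelation ``bg_ar``), plus independent Gaussian measurement noise
  ``bg_noise_sd`` on every stored value.
* HR baseline is context-dependent (sleep / routine / workout means) with
  Gaussian noise ``hr_sd``.
* Tracked sleep sessions run from bedtime to wake time, both displaced by a
  per-night shift ``sleep_shift_mean_min + N(0, sleep_shift_sd_min)`` —
  an irregular sleeper is simulated by a non-zero mean shift, which makes
  tracked nights diverge from the schedule-declared ones.
* Planted patterns **overwrite** the baseline (they are not added to it), so
  the manifest is valid ground truth by construction. Plants are anchored to
  the tracked sleep intervals where the pattern semantics require it.
* Sensor dropout blocks delete both BG and HR samples; blocks are drawn so
  that they never overlap a planted window.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    ISO_FMT,
    dump_patient_config,
    load_patient_config,
    parse_fitbit_hr,
    parse_fitbit_sleep,
    parse_fitbit_workouts,
    parse_libre_export,
    write_events,
)
from .model import (
    AcquisitionMode,
    Channel,
    DaySchedule,
    EventKind,
    EventRecord,
    IntervalAnnotation,
    IntervalKind,
    PatientProfile,
    Sample,
    Thresholds,
)

BG_STEP_MIN = 15
HR_STEP_MIN = 1

#: The ten detectable patterns the default plant layout covers.
DEFAULT_PLANT_PATTERNS = (
    "hypoglycemia",
    "hyperglycemia",
    "bg_increasing",
    "bg_decreasing",
    "bradycardia",
    "tachycardia",
    "rebound_effect",
    "dawn_effect",
    "tachycardia_precedes_hypoglycemia",
    "hypoglycemia_precedes_bradycardia",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one simulated cohort.

    The defaults describe a realistic week of paediatric FGM + tracker data:
    euglycemic mean 120 mg/dL with moderate autocorrelated variability,
    sensor noise of a couple of mg/dL, nightly bedtime jitter of a quarter
    hour, and an occasional multi-hour sensor dropout.
    """

    n_patients: int = 3
    days: int = 7
    seed: int = 0
    start_date: dt.date = dt.date(2020, 3, 2)  # a Monday
    bg_mean: float = 120.0
    bg_sd: float = 15.0
    bg_ar: float = 0.8
    bg_noise_sd: float = 2.0
    hr_sleep: float = 60.0
    hr_routine: float = 72.0
    hr_workout: float = 105.0
    hr_sd: float = 2.0
    plant_margin_bg: float = 20.0
    plant_margin_hr: float = 15.0
    dropout_blocks_per_day: float = 0.25
    dropout_block_min: float = 120.0
    sleep_shift_mean_min: float = 0.0
    sleep_shift_sd_min: float = 15.0
    plant_patterns: tuple[str, ...] = DEFAULT_PLANT_PATTERNS

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.days < 0:
            raise ValueError("n_patients and days must be non-negative")
        unknown = [p for p in self.plant_patterns if p not in DEFAULT_PLANT_PATTERNS]
        if unknown:
            raise ValueError(f"unknown plant pattern(s): {unknown}")
        if self.plant_patterns and self.days and self.days < 6:
            raise ValueError(
                f"the default plant layout spans 6 days; days={self.days} places "
                "planted occurrences outside the simulated span"
            )

    def noiseless(self) -> "ScenarioConfig":
        """Same scenario with every noise source and jitter switched off."""
        return dataclasses.replace(
            self, bg_sd=0.0, bg_noise_sd=0.0, hr_sd=0.0, sleep_shift_sd_min=0.0,
        )


@dataclass(frozen=True)
class PlantedEpisode:
    """Ground truth for one planted occurrence: the episode the matching
    detector is expected to report (first/last contributing sample)."""

    pattern: str
    start: dt.datetime
    end: dt.datetime
    channel: Optional[str] = None


@dataclass
class GroundTruthManifest:
    patient_id: str
    planted: list[PlantedEpisode]
    sleeps: list[IntervalAnnotation]
    workouts: list[IntervalAnnotation]
    dropouts: list[tuple[dt.datetime, dt.datetime]]

    def by_pattern(self, pattern: str) -> list[PlantedEpisode]:
        return [p for p in self.planted if p.pattern == pattern]


@dataclass
class PatientBundle:
    patient_id: str
    profile: PatientProfile
    bg: list[Sample]
    hr: list[Sample]
    sleeps: list[IntervalAnnotation]
    workouts: list[IntervalAnnotation]
    events: list[EventRecord]
    manifest: GroundTruthManifest


_SCHEDULE = DaySchedule(
    breakfast=dt.time(7, 30),
    lunch=dt.time(12, 30),
    dinner=dt.time(19, 30),
    bedtime=dt.time(23, 0),
    wake=dt.time(7, 0),
    snacks=(dt.time(16, 30),),
)
_THRESHOLDS = Thresholds(hypo_mgdl=70.0, hyper_mgdl=180.0, brady_bpm=50.0, tachy_bpm=120.0)


def _default_profile(patient_id: str) -> PatientProfile:
    return PatientProfile(
        patient_id=patient_id,
        schedule={i: _SCHEDULE for i in range(7)},
        thresholds=_THRESHOLDS,
    )


class _Grid:
    """A regular sample grid with in-place overwrites and window queries."""

    def __init__(self, t0: dt.datetime, step_min: int, n: int):
        self.t0 = t0
        self.step = step_min
        self.times = [t0 + dt.timedelta(minutes=step_min * i) for i in range(n)]
        self.values = np.zeros(n)

    def _index_range(self, start: dt.datetime, end: dt.datetime) -> range:
        """Indices of grid points in [start, end)."""
        lo = int(max(0, -((self.t0 - start).total_seconds() // 60) + self.step - 1) // self.step)
        while lo < len(self.times) and self.times[lo] < start:
            lo += 1
        hi = lo
        while hi < len(self.times) and self.times[hi] < end:
            hi += 1
        return range(lo, hi)

    def overwrite_const(self, start: dt.datetime, end: dt.datetime, value: float) -> tuple[dt.datetime, dt.datetime]:
        idx = self._index_range(start, end)
        if not idx:
            raise ValueError(f"planted window {start}-{end} covers no grid samples")
        for i in idx:
            self.values[i] = value
        return self.times[idx[0]], self.times[idx[-1]]

    def overwrite_ramp(self, start: dt.datetime, n_steps: int, v0: float, step_value: float) -> tuple[dt.datetime, dt.datetime]:
        """Overwrite n_steps+1 consecutive grid samples from ``start`` with an
        arithmetic ramp; ``start`` must lie on the grid."""
        offset = (start - self.t0).total_seconds() / 60
        i0 = int(round(offset / self.step))
        if self.times[i0] != start:
            raise ValueError(f"ramp start {start} is off-grid")
        for k in range(n_steps + 1):
            self.values[i0 + k] = v0 + step_value * k
        return start, self.times[i0 + n_steps]


def _plan_plants(
    cfg: ScenarioConfig,
    t0: dt.datetime,
    sleeps: Sequence[IntervalAnnotation],
    thr: Thresholds,
) -> tuple[list[dict], list[PlantedEpisode]]:
    """Fixed plant layout for one patient week, anchored to tracked sleep.

    Returns low-level overwrite operations and the manifest entries
    (basic episodes implied by complex plants are listed too). Layout
    (day offsets from the start of the span):

    * day 0 — daytime hypo 10:00, hyper 14:00, brady 20:30
    * day 1 — BG rising ramp 09:00, falling ramp 15:00, tachy 20:00
    * night of day 1 — tachycardia then hypoglycemia late in tracked sleep
    * night of day 2 — hypoglycemia then bradycardia late in tracked sleep
    * night of day 3 — undisturbed (normal) night, hyperglycemia shortly
      after tracked wake (Dawn Effect)
    * day 4 — hypoglycemia 11:00 then hyperglycemia 13:00 (Rebound Effect)
    """
    want = set(cfg.plant_patterns)
    hypo_v = thr.hypo_mgdl - cfg.plant_margin_bg
    hyper_v = thr.hyper_mgdl + cfg.plant_margin_bg
    brady_v = thr.brady_bpm - cfg.plant_margin_hr
    tachy_v = thr.tachy_bpm + cfg.plant_margin_hr

    def day(d: int, h: int, m: int = 0) -> dt.datetime:
        return t0 + dt.timedelta(days=d, hours=h, minutes=m)

    ops: list[dict] = []
    manifest: list[PlantedEpisode] = []

    def const(channel: Channel, pattern: str, start: dt.datetime, minutes: float, value: float) -> dict:
        op = {
            "channel": channel,
            "pattern": pattern,
            "start": start,
            "end": start + dt.timedelta(minutes=minutes),
            "value": value,
        }
        ops.append(op)
        return op

    if "hypoglycemia" in want:
        const(Channel.BG, "hypoglycemia", day(0, 10), 30, hypo_v)
    if "hyperglycemia" in want:
        const(Channel.BG, "hyperglycemia", day(0, 14), 45, hyper_v)
    if "bradycardia" in want:
        const(Channel.HR, "bradycardia", day(0, 20, 30), 10, brady_v)
    if "tachycardia" in want:
        const(Channel.HR, "tachycardia", day(1, 20), 10, tachy_v)
    if "bg_increasing" in want:
        ops.append({"channel": Channel.BG, "pattern": "bg_increasing", "ramp": True,
                    "start": day(1, 9), "n_steps": 4, "v0": 95.0, "step_value": 20.0})
    if "bg_decreasing" in want:
        ops.append({"channel": Channel.BG, "pattern": "bg_decreasing", "ramp": True,
                    "start": day(1, 15), "n_steps": 4, "v0": 175.0, "step_value": -20.0})

    def sleep_anchor(i: int, offset_min: float) -> dt.datetime:
        return sleeps[i].start + dt.timedelta(minutes=offset_min)

    if "tachycardia_precedes_hypoglycemia" in want:
        # BG grid points are anchored to midnight, not to the (shifted) sleep
        # start, so the first BG sample inside the window can trail it by up
        # to 14 min; the 385-min offset keeps the PRECEDES gap within 30 min.
        a = const(Channel.HR, "tachycardia", sleep_anchor(1, 360), 10, tachy_v)
        b = const(Channel.BG, "hypoglycemia", sleep_anchor(1, 385), 30, hypo_v)
        ops.append({"complex": "tachycardia_precedes_hypoglycemia", "a": a, "b": b})
    if "hypoglycemia_precedes_bradycardia" in want:
        a = const(Channel.BG, "hypoglycemia", sleep_anchor(2, 360), 30, hypo_v)
        b = const(Channel.HR, "bradycardia", sleep_anchor(2, 400), 10, brady_v)
        ops.append({"complex": "hypoglycemia_precedes_bradycardia", "a": a, "b": b})
    if "dawn_effect" in want:
        wake = sleeps[3].end
        a = const(Channel.BG, "hyperglycemia", wake + dt.timedelta(minutes=15), 45, hyper_v)
        ops.append({"complex": "dawn_effect", "night": sleeps[3], "a": a})
    if "rebound_effect" in want:
        a = const(Channel.BG, "hypoglycemia", day(4, 11), 30, hypo_v)
        b = const(Channel.BG, "hyperglycemia", day(4, 13), 45, hyper_v)
        ops.append({"complex": "rebound_effect", "a": a, "b": b})
    return ops, manifest


def simulate_patient(cfg: ScenarioConfig, patient_index: int) -> PatientBundle:
    """Simulate one patient: profile, BG/HR grids, tracker sessions, events
    and the ground-truth manifest of every planted pattern occurrence."""
    rng = np.random.default_rng([int(cfg.seed) % (2**31), patient_index])
    pid = f"sim{patient_index:03d}"
    profile = _default_profile(pid)
    t0 = dt.datetime.combine(cfg.start_date, dt.time(0, 0))
    t_end = t0 + dt.timedelta(days=cfg.days)

    # tracked sleep: one session per bedtime, last bedtime excluded so that
    # every session ends within the simulated span
    sleeps: list[IntervalAnnotation] = []
    for d in range(max(0, cfg.days - 1)):
        shift = cfg.sleep_shift_mean_min + rng.normal(0.0, cfg.sleep_shift_sd_min)
        shift_td = dt.timedelta(minutes=round(shift))
        start = dt.datetime.combine(cfg.start_date + dt.timedelta(days=d), _SCHEDULE.bedtime) + shift_td
        end = dt.datetime.combine(cfg.start_date + dt.timedelta(days=d + 1), _SCHEDULE.wake) + shift_td
        sleeps.append(
            IntervalAnnotation(start=start, end=end, kind=IntervalKind.SLEEP,
                               minutes_awake=float(rng.integers(0, 20)),
                               minutes_restless=float(rng.integers(0, 30)))
        )
    workouts = [
        IntervalAnnotation(
            start=dt.datetime.combine(cfg.start_date + dt.timedelta(days=d), dt.time(17, 30)),
            end=dt.datetime.combine(cfg.start_date + dt.timedelta(days=d), dt.time(18, 15)),
            kind=IntervalKind.WORKOUT,
            intensity=2,
        )
        for d in range(cfg.days)
        if d % 2 == 0
    ]

    # baseline grids
    n_bg = cfg.days * 24 * 60 // BG_STEP_MIN
    n_hr = cfg.days * 24 * 60 // HR_STEP_MIN
    bg_grid = _Grid(t0, BG_STEP_MIN, n_bg)
    hr_grid = _Grid(t0, HR_STEP_MIN, n_hr)

    innov_sd = cfg.bg_sd * float(np.sqrt(1.0 - cfg.bg_ar**2))
    x = cfg.bg_mean + rng.normal(0.0, cfg.bg_sd) if cfg.bg_sd else cfg.bg_mean
    for i in range(n_bg):
        bg_grid.values[i] = x
        x = cfg.bg_mean + cfg.bg_ar * (x - cfg.bg_mean) + (rng.normal(0.0, innov_sd) if innov_sd else 0.0)

    in_sleep = np.zeros(n_hr, dtype=bool)
    in_workout = np.zeros(n_hr, dtype=bool)
    for iv, mask in ((sleeps, in_sleep), (workouts, in_workout)):
        for interval in iv:
            lo = max(0, int((interval.start - t0).total_seconds() // 60))
            hi = min(n_hr, int((interval.end - t0).total_seconds() // 60))
            mask[lo:hi] = True
    hr_base = np.where(in_sleep, cfg.hr_sleep, np.where(in_workout, cfg.hr_workout, cfg.hr_routine))
    hr_grid.values[:] = hr_base + (rng.normal(0.0, cfg.hr_sd, n_hr) if cfg.hr_sd else 0.0)

    # plants overwrite the baseline; manifest records actual grid boundaries
    planted: list[PlantedEpisode] = []
    protected: list[tuple[dt.datetime, dt.datetime]] = []
    if cfg.plant_patterns and cfg.days:
        ops, _ = _plan_plants(cfg, t0, sleeps, profile.thresholds)
        realised: dict[int, tuple[dt.datetime, dt.datetime]] = {}
        for op in ops:
            if "complex" in op:
                continue
            grid = bg_grid if op["channel"] is Channel.BG else hr_grid
            if op.get("ramp"):
                first, last = grid.overwrite_ramp(op["start"], op["n_steps"], op["v0"], op["step_value"])
                end_prot = last
            else:
                if op["end"] > t_end:
                    raise ValueError(f"planted pattern outside simulated span: {op['pattern']} at {op['start']}")
                first, last = grid.overwrite_const(op["start"], op["end"], op["value"])
                end_prot = op["end"]
            realised[id(op)] = (first, last)
            protected.append((op["start"] - dt.timedelta(minutes=1), end_prot + dt.timedelta(minutes=1)))
            planted.append(PlantedEpisode(op["pattern"], first, last, op["channel"].value))
        for op in ops:
            if "complex" not in op:
                continue
            name = op["complex"]
            if name == "dawn_effect":
                first_a, last_a = realised[id(op["a"])]
                planted.append(PlantedEpisode(name, op["night"].start, last_a, Channel.BG.value))
            else:
                first_a, _ = realised[id(op["a"])]
                _, last_b = realised[id(op["b"])]
                planted.append(PlantedEpisode(name, first_a, last_b, None))

    # measurement noise on every stored BG value (plants included)
    if cfg.bg_noise_sd:
        bg_grid.values += rng.normal(0.0, cfg.bg_noise_sd, n_bg)
    np.clip(bg_grid.values, 20.0, None, out=bg_grid.values)
    np.clip(hr_grid.values, 25.0, None, out=hr_grid.values)

    # sensor dropout blocks delete both BG and HR samples
    dropouts: list[tuple[dt.datetime, dt.datetime]] = []
    for d in range(cfg.days):
        if rng.random() >= cfg.dropout_blocks_per_day:
            continue
        for _attempt in range(10):
            start_min = float(rng.uniform(0, 24 * 60 - cfg.dropout_block_min))
            b0 = t0 + dt.timedelta(days=d, minutes=round(start_min))
            b1 = b0 + dt.timedelta(minutes=cfg.dropout_block_min)
            if all(b1 <= p0 or b0 >= p1 for p0, p1 in protected):
                dropouts.append((b0, b1))
                break

    def _dropped(ts: dt.datetime) -> bool:
        return any(b0 <= ts < b1 for b0, b1 in dropouts)

    bg = [
        Sample(ts, Channel.BG, float(v), AcquisitionMode.AUTO)
        for ts, v in zip(bg_grid.times, bg_grid.values)
        if not _dropped(ts)
    ]
    hr = [
        Sample(ts, Channel.HR, float(v), AcquisitionMode.NA)
        for ts, v in zip(hr_grid.times, hr_grid.values)
        if not _dropped(ts)
    ]

    events = [EventRecord(s.timestamp, EventKind.BG_AUTO, value=s.value) for s in bg]
    for d in range(cfg.days):
        day = cfg.start_date + dt.timedelta(days=d)
        for meal_time in (_SCHEDULE.breakfast, _SCHEDULE.lunch, _SCHEDULE.dinner):
            ts = dt.datetime.combine(day, meal_time)
            events.append(EventRecord(ts, EventKind.MEAL))
            events.append(EventRecord(ts + dt.timedelta(minutes=10), EventKind.INSULIN,
                                      value=float(rng.integers(2, 8))))
    events.sort(key=lambda e: e.timestamp)

    manifest = GroundTruthManifest(
        patient_id=pid, planted=planted, sleeps=list(sleeps), workouts=list(workouts),
        dropouts=dropouts,
    )
    return PatientBundle(pid, profile, bg, hr, sleeps, workouts, events, manifest)


def simulate_cohort(cfg: ScenarioConfig) -> list[PatientBundle]:
    return [simulate_patient(cfg, i) for i in range(cfg.n_patients)]


# ---------------------------------------------------------------------------
# File emission in the exact dialects the parsers read
# ---------------------------------------------------------------------------

def _hr_day_docs(hr: Sequence[Sample]) -> list[dict]:
    by_day: dict[dt.date, list[Sample]] = {}
    for s in hr:
        by_day.setdefault(s.timestamp.date(), []).append(s)
    return [
        {
            "activities-heart": [{"dateTime": day.isoformat()}],
            "activities-heart-intraday": {
                "datasetInterval": 1,
                "datasetType": "minute",
                "dataset": [
                    {"time": s.timestamp.time().isoformat(timespec="seconds"), "value": s.value}
                    for s in samples
                ],
            },
        }
        for day, samples in sorted(by_day.items())
    ]


def manifest_to_dict(manifest: GroundTruthManifest) -> dict:
    return {
        "patient_id": manifest.patient_id,
        "planted": [
            {"pattern": p.pattern, "start": p.start.strftime(ISO_FMT),
             "end": p.end.strftime(ISO_FMT), "channel": p.channel}
            for p in manifest.planted
        ],
        "sleeps": [
            {"start": iv.start.strftime(ISO_FMT), "end": iv.end.strftime(ISO_FMT),
             "minutes_awake": iv.minutes_awake, "minutes_restless": iv.minutes_restless}
            for iv in manifest.sleeps
        ],
        "workouts": [
            {"start": iv.start.strftime(ISO_FMT), "end": iv.end.strftime(ISO_FMT),
             "intensity": iv.intensity}
            for iv in manifest.workouts
        ],
        "dropouts": [[a.strftime(ISO_FMT), b.strftime(ISO_FMT)] for a, b in manifest.dropouts],
    }


def manifest_from_dict(doc: dict) -> GroundTruthManifest:
    parse = lambda s: dt.datetime.strptime(s, ISO_FMT)
    return GroundTruthManifest(
        patient_id=doc["patient_id"],
        planted=[
            PlantedEpisode(p["pattern"], parse(p["start"]), parse(p["end"]), p.get("channel"))
            for p in doc["planted"]
        ],
        sleeps=[
            IntervalAnnotation(start=parse(s["start"]), end=parse(s["end"]),
                               kind=IntervalKind.SLEEP,
                               minutes_awake=s.get("minutes_awake"),
                               minutes_restless=s.get("minutes_restless"))
            for s in doc["sleeps"]
        ],
        workouts=[
            IntervalAnnotation(start=parse(w["start"]), end=parse(w["end"]),
                               kind=IntervalKind.WORKOUT, intensity=w.get("intensity"))
            for w in doc["workouts"]
        ],
        dropouts=[(parse(a), parse(b)) for a, b in doc["dropouts"]],
    )


def emit_files(bundle: PatientBundle, out_dir: Path) -> dict[str, Path]:
    """Write one patient bundle as the three input dialects plus manifest.

    Files parse back (via :mod:`glycta.io_formats`) to the bundle exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "libre": out_dir / "libre.tsv",
        "hr": out_dir / "hr.json",
        "sleep": out_dir / "sleep.json",
        "workouts": out_dir / "workouts.json",
        "config": out_dir / "patient.yaml",
        "manifest": out_dir / "manifest.json",
    }
    with paths["libre"].open("w") as fh:
        write_events(bundle.events, fh)
    paths["hr"].write_text(json.dumps(_hr_day_docs(bundle.hr), indent=1))
    paths["sleep"].write_text(
        json.dumps(
            {"sleep": [
                {"startTime": iv.start.strftime(ISO_FMT), "endTime": iv.end.strftime(ISO_FMT),
                 "minutesAwake": iv.minutes_awake, "minutesRestless": iv.minutes_restless}
                for iv in bundle.sleeps
            ]}, indent=1)
    )
    paths["workouts"].write_text(
        json.dumps(
            {"activities": [
                {"startTime": iv.start.strftime(ISO_FMT), "endTime": iv.end.strftime(ISO_FMT),
                 "intensity": iv.intensity}
                for iv in bundle.workouts
            ]}, indent=1)
    )
    paths["config"].write_text(dump_patient_config(bundle.profile))
    paths["manifest"].write_text(json.dumps(manifest_to_dict(bundle.manifest), indent=1))
    return paths


def load_bundle(in_dir: Path) -> PatientBundle:
    """Parse an emitted patient directory back into a bundle."""
    in_dir = Path(in_dir)
    events, _ = parse_libre_export((in_dir / "libre.tsv").read_text())
    hr, _ = parse_fitbit_hr(json.loads((in_dir / "hr.json").read_text()))
    sleeps, _ = parse_fitbit_sleep(json.loads((in_dir / "sleep.json").read_text()))
    workouts, _ = parse_fitbit_workouts(json.loads((in_dir / "workouts.json").read_text()))
    profile = load_patient_config((in_dir / "patient.yaml").read_text())
    manifest = manifest_from_dict(json.loads((in_dir / "manifest.json").read_text()))
    bg = [e.to_sample() for e in events if e.kind in (EventKind.BG_AUTO, EventKind.BG_SCAN)]
    return PatientBundle(profile.patient_id, profile, bg, hr, sleeps, workouts, events, manifest)
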