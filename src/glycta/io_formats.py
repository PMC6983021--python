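"""Readers and writers for the three input dialects and the tabular outputs.

Three families of inputs are supported:

* an FGM reader export (tab- or comma-separated, one event per row) in the
  style of the public FreeStyle Libre text export, with a fully configurable
  column mapping (:class:`LibreDialect`);
* activity-tracker JSON documents (intraday heart rate, sleep log, workout
  log) shaped as a minimal subset of the public Fitbit Web API responses;
* a per-patient YAML/JSON config holding the weekday habit schedule and the
  four alert thresholds.

Parsers never impute: holes in the input appear as holes in the output, and
every parser returns a :class:`ParseReport` describing what was read, kept,
skipped and merged. Timestamps are written back in ISO-8601.
"""

from __future__ import annotations

import csv
import datetime as dt
import io
import json
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Union

import yaml

from .model import (
    AcquisitionMode,
    Channel,
    DaySchedule,
    Episode,
    EventKind,
    EventRecord,
    IntervalAnnotation,
    IntervalKind,
    PatientProfile,
    ProfileValidationError,
    Sample,
    Thresholds,
    WEEKDAYS,
)

logger = logging.getLogger(__name__)

ISO_FMT = "%Y-%m-%dT%H:%M:%S"


class FormatError(ValueError):
    """Raised when an input document does not match the expected dialect."""


@dataclass
class ParseReport:
    """Accounting of one parse: rows seen, kept, skipped, and soft errors."""

    rows_read: int = 0
    rows_kept: int = 0
    rows_skipped: int = 0
    duplicates_dropped: int = 0
    merges: int = 0
    errors: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class LibreDialect:
    """Column mapping for the FGM reader export.

    The default mapping follows the public FreeStyle Libre text export:
    a ``Record Type`` code selects the event kind and kind-specific value
    columns hold the payload. Export layouts vary by software version, so
    every element of the mapping is configurable.
    """

    timestamp_col: str = "Time"
    record_type_col: str = "Record Type"
    #: record-type code (as it appears in the file) -> event kind
    kind_codes: dict[str, EventKind] = field(
        default_factory=lambda: {
            "0": EventKind.BG_AUTO,
            "1": EventKind.BG_SCAN,
            "4": EventKind.INSULIN,
            "5": EventKind.MEAL,
            "6": EventKind.HEALTH_NOTE,
        }
    )
    value_cols: dict[EventKind, str] = field(
        default_factory=lambda: {
            EventKind.BG_AUTO: "Historic Glucose (mg/dL)",
            EventKind.BG_SCAN: "Scan Glucose (mg/dL)",
            EventKind.INSULIN: "Rapid-Acting Insulin (units)",
        }
    )
    note_col: str = "Notes"
    timestamp_format: str = "%Y-%m-%d %H:%M"

    def code_for(self, kind: EventKind) -> str:
        for code, k in self.kind_codes.items():
            if k is kind:
                return code
        raise KeyError(kind)


DEFAULT_LIBRE_DIALECT = LibreDialect()


def _sniff_delimiter(header: str) -> str:
    return "\t" if "\t" in header else ","


def parse_libre_export(
    stream: Union[IO[str], str],
    dialect: LibreDialect = DEFAULT_LIBRE_DIALECT,
) -> tuple[list[EventRecord], ParseReport]:
    """Parse an FGM reader export into a timestamp-sorted event list.

    Rows whose record-type code is not in the dialect mapping are skipped and
    counted. Malformed rows (bad timestamp, non-numeric value) are collected
    as row-level errors; if more than half of the data rows fail, a
    :class:`FormatError` naming the first offending row is raised.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    report = ParseReport()
    lines = text.splitlines()
    if not lines:
        return [], report
    delim = _sniff_delimiter(lines[0])
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    if reader.fieldnames is None or dialect.timestamp_col not in reader.fieldnames:
        raise FormatError(
            f"header lacks timestamp column {dialect.timestamp_col!r}: {reader.fieldnames}"
        )
    events: list[EventRecord] = []
    first_bad: Optional[int] = None
    n_failed = 0
    for lineno, row in enumerate(reader, start=2):
        report.rows_read += 1
        code = (row.get(dialect.record_type_col) or "").strip()
        if code not in dialect.kind_codes:
            report.rows_skipped += 1
            continue
        kind = dialect.kind_codes[code]
        try:
            ts = dt.datetime.strptime(row[dialect.timestamp_col].strip(), dialect.timestamp_format)
            value = None
            note = None
            if kind in dialect.value_cols:
                value = float(row[dialect.value_cols[kind]])
            if kind is EventKind.HEALTH_NOTE:
                note = (row.get(dialect.note_col) or "").strip() or None
            events.append(EventRecord(ts, kind, value=value, note=note))
            report.rows_kept += 1
        except (ValueError, KeyError, TypeError) as exc:
            n_failed += 1
            report.errors.append(f"line {lineno}: {exc}")
            if first_bad is None:
                first_bad = lineno
    n_data = report.rows_read - report.rows_skipped
    if n_data and n_failed > n_data / 2:
        raise FormatError(
            f"{n_failed}/{n_data} rows failed to parse; first offending row is line {first_bad}"
        )
    events.sort(key=lambda e: e.timestamp)
    return events, report


def write_events(
    events: Iterable[EventRecord],
    stream: IO[str],
    dialect: LibreDialect = DEFAULT_LIBRE_DIALECT,
) -> None:
    """Write events back in the configured export dialect (tab-separated)."""
    cols = [dialect.timestamp_col, dialect.record_type_col]
    cols += [dialect.value_cols[k] for k in (EventKind.BG_AUTO, EventKind.BG_SCAN, EventKind.INSULIN)]
    cols.append(dialect.note_col)
    writer = csv.DictWriter(stream, fieldnames=cols, delimiter="\t", lineterminator="\n")
    writer.writeheader()
    for ev in sorted(events, key=lambda e: e.timestamp):
        row = {c: "" for c in cols}
        row[dialect.timestamp_col] = ev.timestamp.strftime(dialect.timestamp_format)
        row[dialect.record_type_col] = dialect.code_for(ev.kind)
        if ev.kind in dialect.value_cols:
            # str() keeps the shortest exact decimal so round trips are lossless
            row[dialect.value_cols[ev.kind]] = str(ev.value)
        if ev.note:
            row[dialect.note_col] = ev.note
        writer.writerow(row)


# ---------------------------------------------------------------------------
# Fitbit-style JSON
# ---------------------------------------------------------------------------

def _require(doc: dict, key: str) -> object:
    if key not in doc:
        raise FormatError(f"document lacks required field {key!r}")
    return doc[key]


def parse_fitbit_hr(doc: Union[dict, list]) -> tuple[list[Sample], ParseReport]:
    """Parse intraday heart-rate JSON into minute-resolution HR samples.

    ``doc`` is a single day document shaped like the Fitbit Web API intraday
    response (``activities-heart`` carries the date, ``activities-heart-
    intraday.dataset`` the ``{time, value}`` pairs), or a list of such
    documents. Duplicate minutes keep the last value and are counted; holes
    are preserved, never filled.
    """
    docs = doc if isinstance(doc, list) else [doc]
    report = ParseReport()
    by_minute: dict[dt.datetime, float] = {}
    for d in docs:
        heads = _require(d, "activities-heart")
        if not heads or "dateTime" not in heads[0]:
            raise FormatError("document lacks required field 'dateTime'")
        day = dt.date.fromisoformat(heads[0]["dateTime"])
        intraday = _require(d, "activities-heart-intraday")
        for entry in intraday.get("dataset", []):
            report.rows_read += 1
            t = dt.time.fromisoformat(entry["time"])
            ts = dt.datetime.combine(day, t).replace(second=0, microsecond=0)
            if ts in by_minute:
                report.duplicates_dropped += 1
            by_minute[ts] = float(entry["value"])
    if report.duplicates_dropped:
        logger.info("HR parse: %d duplicate minutes dropped (kept last)", report.duplicates_dropped)
    samples = [
        Sample(ts, Channel.HR, v, AcquisitionMode.NA) for ts, v in sorted(by_minute.items())
    ]
    report.rows_kept = len(samples)
    return samples, report


def _merge_intervals(
    intervals: list[IntervalAnnotation], report: ParseReport
) -> list[IntervalAnnotation]:
    """Union overlapping same-kind intervals; attribute minutes are summed."""
    if not intervals:
        return []
    intervals = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    merged = [intervals[0]]
    for iv in intervals[1:]:
        prev = merged[-1]
        if iv.start <= prev.end:  # overlap or touch
            report.merges += 1
            logger.info("merging overlapping %s intervals %s and %s", iv.kind.value, prev, iv)

            def _add(a, b):
                if a is None and b is None:
                    return None
                return (a or 0) + (b or 0)

            merged[-1] = IntervalAnnotation(
                start=prev.start,
                end=max(prev.end, iv.end),
                kind=prev.kind,
                intensity=max(filter(lambda x: x is not None, (prev.intensity, iv.intensity)), default=None),
                minutes_awake=_add(prev.minutes_awake, iv.minutes_awake),
                minutes_restless=_add(prev.minutes_restless, iv.minutes_restless),
            )
        else:
            merged.append(iv)
    return merged


def _parse_dt(s: str) -> dt.datetime:
    # Fitbit emits "2019-03-01T23:10:00.000"; tolerate a trailing millisecond part
    return dt.datetime.fromisoformat(s.split(".")[0]).replace(second=0, microsecond=0)


def parse_fitbit_sleep(doc: dict) -> tuple[list[IntervalAnnotation], ParseReport]:
    """Parse a sleep-log JSON document into merged sleep intervals.

    Each entry of the ``sleep`` array must carry ``startTime`` and
    ``endTime`` (ISO-8601); ``minutesAwake`` and ``minutesRestless`` are
    optional. Records with ``end <= start`` are collected as record-level
    errors; overlapping records are merged and the merge logged.
    """
    report = ParseReport()
    out: list[IntervalAnnotation] = []
    for i, rec in enumerate(_require(doc, "sleep")):
        report.rows_read += 1
        try:
            start = _parse_dt(rec["startTime"])
            end = _parse_dt(rec["endTime"])
            out.append(
                IntervalAnnotation(
                    start=start,
                    end=end,
                    kind=IntervalKind.SLEEP,
                    minutes_awake=rec.get("minutesAwake"),
                    minutes_restless=rec.get("minutesRestless"),
                )
            )
            report.rows_kept += 1
        except (ValueError, KeyError) as exc:
            report.errors.append(f"sleep record {i}: {exc}")
    return _merge_intervals(out, report), report


def parse_fitbit_workouts(doc: dict) -> tuple[list[IntervalAnnotation], ParseReport]:
    """Parse a workout-log JSON document into merged workout intervals.

    Each entry of the ``activities`` array carries ``startTime`` (ISO-8601)
    and either ``endTime`` or ``duration`` in milliseconds, plus an optional
    ordinal ``intensity``.
    """
    report = ParseReport()
    out: list[IntervalAnnotation] = []
    for i, rec in enumerate(_require(doc, "activities")):
        report.rows_read += 1
        try:
            start = _parse_dt(rec["startTime"])
            if "endTime" in rec:
                end = _parse_dt(rec["endTime"])
            else:
                end = start + dt.timedelta(milliseconds=float(rec["duration"]))
            out.append(
                IntervalAnnotation(
                    start=start, end=end, kind=IntervalKind.WORKOUT,
                    intensity=rec.get("intensity"),
                )
            )
            report.rows_kept += 1
        except (ValueError, KeyError) as exc:
            report.errors.append(f"workout record {i}: {exc}")
    return _merge_intervals(out, report), report


# ---------------------------------------------------------------------------
# Patient config
# ---------------------------------------------------------------------------

def _parse_time(s: object) -> dt.time:
    if isinstance(s, dt.time):
        return s
    return dt.time.fromisoformat(str(s))


def load_patient_config(doc: Union[dict, str, IO[str]]) -> PatientProfile:
    """Load and validate a patient config (YAML/JSON text, stream or dict).

    Expected shape::

        patient_id: p01
        thresholds: {hypo_mgdl: 70, hyper_mgdl: 180, brady_bpm: 50, tachy_bpm: 120}
        schedule:
          monday: {breakfast: "07:30", lunch: "12:30", dinner: "19:30",
                   snacks: ["16:30"], bedtime: "23:00", wake: "07:00"}
          ...   # all seven weekdays required

    All violations are collected and reported together in a single
    :class:`~glycta.model.ProfileValidationError`.
    """
    if not isinstance(doc, dict):
        doc = yaml.safe_load(doc if isinstance(doc, str) else doc.read())
    violations: list[str] = []
    thr_doc = doc.get("thresholds", {})
    missing_thr = [k for k in ("hypo_mgdl", "hyper_mgdl", "brady_bpm", "tachy_bpm") if k not in thr_doc]
    if missing_thr:
        violations.append("thresholds missing: " + ", ".join(missing_thr))
    sched_doc = doc.get("schedule", {})
    schedule: dict[int, DaySchedule] = {}
    for i, name in enumerate(WEEKDAYS):
        if name not in sched_doc:
            violations.append(f"schedule missing {name}")
            continue
        day = sched_doc[name]
        try:
            schedule[i] = DaySchedule(
                breakfast=_parse_time(day["breakfast"]),
                lunch=_parse_time(day["lunch"]),
                dinner=_parse_time(day["dinner"]),
                bedtime=_parse_time(day["bedtime"]),
                wake=_parse_time(day["wake"]),
                snacks=tuple(_parse_time(s) for s in day.get("snacks", [])),
            )
        except (KeyError, ValueError) as exc:
            violations.append(f"schedule for {name}: {exc}")
    if not missing_thr:
        thr = Thresholds(**{k: float(thr_doc[k]) for k in ("hypo_mgdl", "hyper_mgdl", "brady_bpm", "tachy_bpm")})
        violations.extend(thr.violations())
    if violations:
        raise ProfileValidationError(violations)
    return PatientProfile(patient_id=str(doc.get("patient_id", "patient")), schedule=schedule, thresholds=thr)


def dump_patient_config(profile: PatientProfile) -> str:
    """Serialise a profile back to the YAML config dialect."""
    doc = {
        "patient_id": profile.patient_id,
        "thresholds": {
            "hypo_mgdl": profile.thresholds.hypo_mgdl,
            "hyper_mgdl": profile.thresholds.hyper_mgdl,
            "brady_bpm": profile.thresholds.brady_bpm,
            "tachy_bpm": profile.thresholds.tachy_bpm,
        },
        "schedule": {
            name: {
                "breakfast": profile.schedule[i].breakfast.isoformat("minutes"),
                "lunch": profile.schedule[i].lunch.isoformat("minutes"),
                "dinner": profile.schedule[i].dinner.isoformat("minutes"),
                "bedtime": profile.schedule[i].bedtime.isoformat("minutes"),
                "wake": profile.schedule[i].wake.isoformat("minutes"),
                "snacks": [s.isoformat("minutes") for s in profile.schedule[i].snacks],
            }
            for i, name in enumerate(WEEKDAYS)
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)


# ---------------------------------------------------------------------------
# Episode tables
# ---------------------------------------------------------------------------

EPISODE_COLUMNS = ["patient_id", "pattern", "start", "end", "duration_min", "context_tag", "details"]


def _component_payload(ep: Episode) -> str:
    if not ep.components:
        return ep.details
    payload = [
        {
            "pattern": c.pattern,
            "start": c.start.strftime(ISO_FMT),
            "end": c.end.strftime(ISO_FMT),
            "n_samples": c.n_samples,
            "duration_min": c.duration_min,
            "channel": c.channel.value if c.channel else None,
            "context_tag": c.context_tag,
        }
        for c in ep.components
    ]
    return json.dumps({"components": payload})


def write_episodes(episodes: Iterable[Episode], stream: IO[str]) -> None:
    """Write episodes as CSV, ordered by (patient, pattern, start)."""
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(EPISODE_COLUMNS + ["n_samples", "channel"])
    for ep in sorted(episodes, key=lambda e: (e.patient_id, e.pattern, e.start)):
        writer.writerow(
            [
                ep.patient_id,
                ep.pattern,
                ep.start.strftime(ISO_FMT),
                ep.end.strftime(ISO_FMT),
                str(ep.duration_min),
                ep.context_tag or "",
                _component_payload(ep),
                ep.n_samples,
                ep.channel.value if ep.channel else "",
            ]
        )


def read_episodes(stream: Union[IO[str], str]) -> list[Episode]:
    """Read back an episode CSV written by :func:`write_episodes`."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    reader = csv.DictReader(stream)
    out: list[Episode] = []
    for row in reader:
        components: tuple[Episode, ...] = ()
        details = row["details"]
        if details.startswith("{"):
            payload = json.loads(details)
            components = tuple(
                Episode(
                    patient_id=row["patient_id"],
                    pattern=c["pattern"],
                    start=dt.datetime.strptime(c["start"], ISO_FMT),
                    end=dt.datetime.strptime(c["end"], ISO_FMT),
                    n_samples=int(c["n_samples"]),
                    duration_min=float(c["duration_min"]),
                    channel=Channel(c["channel"]) if c.get("channel") else None,
                    context_tag=c.get("context_tag"),
                )
                for c in payload["components"]
            )
            details = ""
        out.append(
            Episode(
                patient_id=row["patient_id"],
                pattern=row["pattern"],
                start=dt.datetime.strptime(row["start"], ISO_FMT),
                end=dt.datetime.strptime(row["end"], ISO_FMT),
                n_samples=int(row["n_samples"]),
                duration_min=float(row["duration_min"]),
                channel=Channel(row["channel"]) if row.get("channel") else None,
                context_tag=row["context_tag"] or None,
                components=components,
                details=details,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Internal dataset tables (samples / intervals), used by the CLI
# ---------------------------------------------------------------------------

def write_samples(samples: Iterable[Sample], stream: IO[str]) -> None:
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(["timestamp", "channel", "value", "mode"])
    for s in sorted(samples, key=lambda s: (s.channel.value, s.timestamp)):
        writer.writerow([s.timestamp.strftime(ISO_FMT), s.channel.value, str(s.value), s.mode.value])


def read_samples(stream: Union[IO[str], str]) -> list[Sample]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out = []
    for row in csv.DictReader(stream):
        out.append(
            Sample(
                dt.datetime.strptime(row["timestamp"], ISO_FMT),
                Channel(row["channel"]),
                float(row["value"]),
                AcquisitionMode(row["mode"]),
            )
        )
    return out


def write_intervals(intervals: Iterable[IntervalAnnotation], stream: IO[str]) -> None:
    writer = csv.writer(stream, lineterminator="\n")
    writer.writerow(["start", "end", "kind", "intensity", "minutes_awake", "minutes_restless"])
    for iv in sorted(intervals, key=lambda iv: (iv.start, iv.end)):
        writer.writerow(
            [
                iv.start.strftime(ISO_FMT),
                iv.end.strftime(ISO_FMT),
                iv.kind.value,
                "" if iv.intensity is None else iv.intensity,
                "" if iv.minutes_awake is None else str(iv.minutes_awake),
                "" if iv.minutes_restless is None else str(iv.minutes_restless),
            ]
        )


def read_intervals(stream: Union[IO[str], str]) -> list[IntervalAnnotation]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out = []
    for row in csv.DictReader(stream):
        out.append(
            IntervalAnnotation(
                start=dt.datetime.strptime(row["start"], ISO_FMT),
                end=dt.datetime.strptime(row["end"], ISO_FMT),
                kind=IntervalKind(row["kind"]),
                intensity=int(row["intensity"]) if row["intensity"] else None,
                minutes_awake=float(row["minutes_awake"]) if row["minutes_awake"] else None,
                minutes_restless=float(row["minutes_restless"]) if row["minutes_restless"] else None,
            )
        )
    return out
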