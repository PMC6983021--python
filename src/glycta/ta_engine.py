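"""Temporal-abstraction engine: state, trend and complex pattern detection.

The engine converts the numeric BG/HR series into labeled episodes:

* **state abstraction** — maximal runs of consecutive samples on one side of
  a strict threshold (Hypoglycemia ``BG < hypo``, Hyperglycemia
  ``BG > hyper``, Bradycardia ``HR < brady``, Tachycardia ``HR > tachy``);
* **trend abstraction** — maximal runs of consecutive steps whose rate of
  change, rescaled to a 15-minute basis, meets a minimum slope (BG
  Increasing / Decreasing: at least 15 mg/dL per 15 min sustained for at
  least 35 min);
* **complex patterns** — compositions via the interval relations PRECEDES
  (one episode ends before the other starts, within a maximum gap) and
  DURING (containment in a context interval such as a sleep session):
  Rebound Effect, Dawn Effect, Tachycardia PRECEDES Hypoglycemia (DURING
  sleep) and Hypoglycemia PRECEDES Bradycardia DURING sleep.

Duration conventions: a state episode lasts its sample span plus one nominal
sampling period (a single qualifying BG sample forms a 15-minute episode); a
trend episode lasts the pure span of its first-to-last sample. Runs are
never bridged across sensor dropouts longer than ``max_intra_gap``
(default 30 min for BG — two missed grid samples — and 5 min for HR).
"""

from __future__ import annotations

import datetime as dt
import logging
import operator
from typing import Callable, Iterable, Optional, Sequence

from .model import (
    Channel,
    Direction,
    Episode,
    IntervalAnnotation,
    NOMINAL_PERIOD_MIN,
    PatientProfile,
    PatternSpec,
    PatternType,
    Relation,
    Sample,
    Thresholds,
)
from .tagging import TaggedSample, TagPreference, effective_tag, schedule_night_spans

logger = logging.getLogger(__name__)

#: Default dropout tolerance per channel, minutes: two missed BG grid samples
#: break an episode; HR runs break after 5 silent minutes.
DEFAULT_MAX_INTRA_GAP: dict[Channel, float] = {Channel.BG: 30.0, Channel.HR: 5.0}

#: Trend rates are quoted on a 15-minute basis.
TREND_BASIS_MIN = 15.0

_COMPARATORS: dict[str, Callable[[float, float], bool]] = {"<": operator.lt, ">": operator.gt}


def _span_min(a: dt.datetime, b: dt.datetime) -> float:
    return (b - a).total_seconds() / 60.0


def detect_state_episodes(
    series: Sequence[Sample],
    comparator: str,
    threshold: float,
    max_intra_gap: Optional[float] = None,
    *,
    pattern: str = "state",
    patient_id: str = "",
) -> list[Episode]:
    """Maximal runs of consecutive samples strictly beyond a threshold.

    A run breaks when a sample fails the comparator or when two consecutive
    qualifying samples are more than ``max_intra_gap`` minutes apart. A
    single qualifying sample forms an episode; episode duration is the
    sample span plus one nominal sampling period of the channel.
    """
    if not series:
        return []
    cmp = _COMPARATORS[comparator]
    channel = series[0].channel
    period = NOMINAL_PERIOD_MIN[channel]
    if max_intra_gap is None:
        max_intra_gap = DEFAULT_MAX_INTRA_GAP[channel]
    episodes: list[Episode] = []
    run: list[Sample] = []

    def _flush() -> None:
        if run:
            episodes.append(
                Episode(
                    patient_id=patient_id,
                    pattern=pattern,
                    start=run[0].timestamp,
                    end=run[-1].timestamp,
                    n_samples=len(run),
                    duration_min=_span_min(run[0].timestamp, run[-1].timestamp) + period,
                    channel=channel,
                )
            )
            run.clear()

    for s in series:
        if cmp(s.value, threshold):
            if run and _span_min(run[-1].timestamp, s.timestamp) > max_intra_gap:
                _flush()
            run.append(s)
        else:
            _flush()
    _flush()
    return episodes


def detect_trend_episodes(
    series: Sequence[Sample],
    direction: Direction,
    min_rate: float,
    min_duration: float = 35.0,
    max_intra_gap: Optional[float] = None,
    *,
    pattern: str = "trend",
    patient_id: str = "",
) -> list[Episode]:
    """Maximal runs of consecutive qualifying steps sustained long enough.

    A step between consecutive samples qualifies when its signed change,
    rescaled to a 15-minute basis by the actual spacing, is at least
    ``min_rate`` (increasing) or at most ``-min_rate`` (decreasing), and the
    spacing does not exceed ``max_intra_gap``. Episode duration is the pure
    first-to-last span of the run; runs shorter than ``min_duration`` are
    discarded.
    """
    if len(series) < 2:
        return []
    channel = series[0].channel
    if max_intra_gap is None:
        max_intra_gap = DEFAULT_MAX_INTRA_GAP[channel]
    sign = 1.0 if direction is Direction.INCREASING else -1.0
    episodes: list[Episode] = []
    run_start: Optional[int] = None

    def _flush(last: int) -> None:
        nonlocal run_start
        if run_start is None:
            return
        first, run_start = run_start, None
        span = _span_min(series[first].timestamp, series[last].timestamp)
        if span >= min_duration:
            episodes.append(
                Episode(
                    patient_id=patient_id,
                    pattern=pattern,
                    start=series[first].timestamp,
                    end=series[last].timestamp,
                    n_samples=last - first + 1,
                    duration_min=span,
                    channel=channel,
                )
            )

    for i in range(1, len(series)):
        spacing = _span_min(series[i - 1].timestamp, series[i].timestamp)
        qualifies = (
            0 < spacing <= max_intra_gap
            and sign * (series[i].value - series[i - 1].value) / spacing * TREND_BASIS_MIN
            >= min_rate
        )
        if qualifies:
            if run_start is None:
                run_start = i - 1
        else:
            _flush(i - 1)
    _flush(len(series) - 1)
    return episodes


# ---------------------------------------------------------------------------
# Interval temporal relations
# ---------------------------------------------------------------------------

def precedes(a: Episode, b: Episode, max_gap: float) -> bool:
    """True iff ``a`` ends no later than ``b`` starts, within ``max_gap`` min."""
    return a.end <= b.start and _span_min(a.end, b.start) <= max_gap


def during(a: Episode, container: IntervalAnnotation, mode: str = "full") -> bool:
    """Containment of episode ``a`` in a context interval.

    ``full`` requires the whole episode inside the container; ``start_in``
    only requires the episode to start inside it (half-open on the right).
    """
    if mode == "full":
        return container.start <= a.start and a.end <= container.end
    if mode == "start_in":
        return container.start <= a.start < container.end
    raise ValueError(f"unknown during mode {mode!r}")


# ---------------------------------------------------------------------------
# Complex patterns
# ---------------------------------------------------------------------------

def _greedy_pairs(
    a_eps: Sequence[Episode],
    b_eps: Sequence[Episode],
    accept: Callable[[Episode, Episode], bool],
) -> list[tuple[Episode, Episode]]:
    """Greedy earliest-match pairing: each a takes the earliest unmatched b.

    Deterministic, and each component participates in at most one pair.
    """
    a_sorted = sorted(a_eps, key=lambda e: (e.start, e.end))
    b_sorted = sorted(b_eps, key=lambda e: (e.start, e.end))
    taken = [False] * len(b_sorted)
    pairs = []
    for a in a_sorted:
        for j, b in enumerate(b_sorted):
            if not taken[j] and accept(a, b):
                taken[j] = True
                pairs.append((a, b))
                break
    return pairs


def detect_rebound(
    hypo: Sequence[Episode],
    hyper: Sequence[Episode],
    max_gap: float = 120.0,
    *,
    pattern: str = "rebound_effect",
    patient_id: str = "",
) -> list[Episode]:
    """Rebound Effect: a hypoglycemic episode followed by a hyperglycemic one.

    Each hypo episode is greedily matched to the earliest unmatched hyper
    episode that it PRECEDES within ``max_gap`` minutes; the resulting
    complex episode spans hypo start to hyper end.
    """
    pairs = _greedy_pairs(hypo, hyper, lambda h, H: precedes(h, H, max_gap))
    return [
        Episode(
            patient_id=patient_id or h.patient_id,
            pattern=pattern,
            start=h.start,
            end=H.end,
            n_samples=h.n_samples + H.n_samples,
            duration_min=_span_min(h.start, H.end),
            channel=Channel.BG,
            components=(h, H),
        )
        for h, H in pairs
    ]


def detect_dawn_effect(
    bg: Sequence[Sample],
    nights: Sequence[IntervalAnnotation],
    thresholds: Thresholds,
    wake_window: float = 60.0,
    min_normal_cover: float = 0.9,
    *,
    night_source: str = "fitbit",
    patient_id: str = "",
    pattern: str = "dawn_effect",
    hyper_episodes: Optional[Sequence[Episode]] = None,
) -> list[Episode]:
    """Dawn Effect: a normal-glycemia night followed by hyperglycemia at wake.

    For each night interval, the BG samples inside the night must be normal:
    at least ``min_normal_cover`` of them within [hypo, hyper] and none
    strictly beyond either threshold. The pattern fires when a Hyperglycemia
    episode starts within ``wake_window`` minutes after the night ends; the
    emitted episode spans night start to hyper-episode end and records which
    night source (tracked sleep vs schedule) was used. Nights with no BG
    samples are skipped and logged.
    """
    if hyper_episodes is None:
        hyper_episodes = detect_state_episodes(
            bg, ">", thresholds.hyper_mgdl, pattern="hyperglycemia", patient_id=patient_id
        )
    out: list[Episode] = []
    for night in sorted(nights, key=lambda iv: iv.start):
        inside = [s for s in bg if night.start <= s.timestamp < night.end]
        if not inside:
            logger.info("dawn effect: night %s-%s has no BG samples, skipped", night.start, night.end)
            continue
        n_normal = sum(1 for s in inside if thresholds.hypo_mgdl <= s.value <= thresholds.hyper_mgdl)
        breached = any(
            s.value < thresholds.hypo_mgdl or s.value > thresholds.hyper_mgdl for s in inside
        )
        if breached or n_normal / len(inside) < min_normal_cover:
            continue
        wake_limit = night.end + dt.timedelta(minutes=wake_window)
        hyper = next(
            (H for H in sorted(hyper_episodes, key=lambda e: e.start)
             if night.end <= H.start <= wake_limit),
            None,
        )
        if hyper is None:
            continue
        out.append(
            Episode(
                patient_id=patient_id,
                pattern=pattern,
                start=night.start,
                end=hyper.end,
                n_samples=len(inside) + hyper.n_samples,
                duration_min=_span_min(night.start, hyper.end),
                channel=Channel.BG,
                context_tag=night_source,
                components=(hyper,),
            )
        )
    return out


def detect_sequence_in_context(
    a_eps: Sequence[Episode],
    b_eps: Sequence[Episode],
    context: Sequence[IntervalAnnotation],
    relation_gap: float = 30.0,
    during_mode: str = "full",
    *,
    pattern: str = "sequence",
    patient_id: str = "",
    require_context: bool = True,
) -> list[Episode]:
    """Pairs (a, b) with a PRECEDES b, both DURING one shared context interval.

    Matching is greedy earliest-first; every reported pair shares a single
    context interval that contains both components under ``during_mode``.
    With ``require_context=False`` the containment condition is waived (for
    the pattern variant whose sleep context is optional).
    """

    def accept(a: Episode, b: Episode) -> bool:
        if not precedes(a, b, relation_gap):
            return False
        if not require_context:
            return True
        return any(
            during(a, c, during_mode) and during(b, c, during_mode) for c in context
        )

    pairs = _greedy_pairs(a_eps, b_eps, accept)
    return [
        Episode(
            patient_id=patient_id or a.patient_id,
            pattern=pattern,
            start=a.start,
            end=b.end,
            n_samples=a.n_samples + b.n_samples,
            duration_min=_span_min(a.start, b.end),
            context_tag="sleep" if require_context else None,
            components=(a, b),
        )
        for a, b in pairs
    ]


def filter_episodes_by_context(
    eps: Iterable[Episode],
    tagged: Sequence[TaggedSample],
    tag: str,
    preference: TagPreference = TagPreference.FITBIT_FIRST,
    mode: str = "strict",
) -> list[Episode]:
    """Restrict episodes to a day context given the tagged sample series.

    An episode is kept when the effective tags of the samples it spans (on
    its own channel, if set) are all equal to ``tag`` (``strict``) or when
    more than half of them are (``majority``). Episodes spanning no tagged
    samples are dropped.
    """
    if mode not in ("strict", "majority"):
        raise ValueError(f"unknown filter mode {mode!r}")
    out = []
    for ep in eps:
        labels = [
            effective_tag(ts, preference)
            for ts in tagged
            if ep.start <= ts.sample.timestamp <= ep.end
            and (ep.channel is None or ts.sample.channel is ep.channel)
        ]
        if not labels:
            continue
        hits = sum(1 for lab in labels if lab == tag)
        keep = hits == len(labels) if mode == "strict" else hits > len(labels) / 2
        if keep:
            out.append(
                Episode(
                    patient_id=ep.patient_id,
                    pattern=ep.pattern,
                    start=ep.start,
                    end=ep.end,
                    n_samples=ep.n_samples,
                    duration_min=ep.duration_min,
                    channel=ep.channel,
                    context_tag=tag,
                    components=ep.components,
                    details=ep.details,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Pattern catalogue and orchestration
# ---------------------------------------------------------------------------

def default_pattern_specs(thresholds: Thresholds) -> dict[str, PatternSpec]:
    """The ten-pattern catalogue, parameterised by the patient's thresholds.

    Hypo/hyper/brady/tachy thresholds are patient-specific; the trend
    parameters (≥15 mg/dL per 15 min for ≥35 min) and the severe-excursion
    thresholds (BG < 50, BG > 250 mg/dL) are the standard clinical settings.
    """
    t = thresholds
    return {
        "hypoglycemia": PatternSpec("hypoglycemia", PatternType.STATE, Channel.BG, "<", t.hypo_mgdl),
        "hyperglycemia": PatternSpec("hyperglycemia", PatternType.STATE, Channel.BG, ">", t.hyper_mgdl),
        "severe_hypoglycemia": PatternSpec("severe_hypoglycemia", PatternType.STATE, Channel.BG, "<", 50.0),
        "severe_hyperglycemia": PatternSpec("severe_hyperglycemia", PatternType.STATE, Channel.BG, ">", 250.0),
        "bg_increasing": PatternSpec(
            "bg_increasing", PatternType.TREND, Channel.BG,
            direction=Direction.INCREASING, min_rate=15.0, min_duration=35.0,
        ),
        "bg_decreasing": PatternSpec(
            "bg_decreasing", PatternType.TREND, Channel.BG,
            direction=Direction.DECREASING, min_rate=15.0, min_duration=35.0,
        ),
        "bradycardia": PatternSpec("bradycardia", PatternType.STATE, Channel.HR, "<", t.brady_bpm),
        "tachycardia": PatternSpec("tachycardia", PatternType.STATE, Channel.HR, ">", t.tachy_bpm),
        "rebound_effect": PatternSpec(
            "rebound_effect", PatternType.COMPLEX, relation=Relation.PRECEDES, max_gap=120.0
        ),
        "dawn_effect": PatternSpec(
            "dawn_effect", PatternType.COMPLEX, relation=Relation.DURING, max_gap=60.0, context="night"
        ),
        "tachycardia_precedes_hypoglycemia": PatternSpec(
            "tachycardia_precedes_hypoglycemia", PatternType.COMPLEX,
            relation=Relation.PRECEDES, max_gap=30.0, context="sleep",
        ),
        "hypoglycemia_precedes_bradycardia": PatternSpec(
            "hypoglycemia_precedes_bradycardia", PatternType.COMPLEX,
            relation=Relation.PRECEDES, max_gap=30.0, context="sleep",
        ),
    }


def detect_patterns(
    bg: Sequence[Sample],
    hr: Sequence[Sample],
    profile: PatientProfile,
    sleeps: Sequence[IntervalAnnotation] = (),
    patterns: Optional[Iterable[str]] = None,
    *,
    night_source: str = "fitbit",
    wake_window: float = 60.0,
    min_normal_cover: float = 0.9,
    sequence_gap: float = 30.0,
    rebound_gap: float = 120.0,
    sequence_context_required: bool = True,
) -> dict[str, list[Episode]]:
    """Run the requested detectors (default: all) and return episodes by name.

    Complex patterns are built from the basic episode streams detected here;
    the sleep context for the multivariate sequences and the night spans for
    the Dawn Effect come from tracked sleep when ``night_source='fitbit'``
    (the default), else from the schedule-derived night spans.
    """
    specs = default_pattern_specs(profile.thresholds)
    names = list(specs) if patterns is None else list(patterns)
    unknown = [n for n in names if n not in specs]
    if unknown:
        raise KeyError(
            f"unknown pattern(s) {unknown}; valid names: {', '.join(sorted(specs))}"
        )
    pid = profile.patient_id

    def state(name: str, series: Sequence[Sample]) -> list[Episode]:
        sp = specs[name]
        return detect_state_episodes(series, sp.comparator, sp.threshold, pattern=name, patient_id=pid)

    def trend(name: str, series: Sequence[Sample]) -> list[Episode]:
        sp = specs[name]
        return detect_trend_episodes(
            series, sp.direction, sp.min_rate, sp.min_duration, pattern=name, patient_id=pid
        )

    basics = {
        "hypoglycemia": lambda: state("hypoglycemia", bg),
        "hyperglycemia": lambda: state("hyperglycemia", bg),
        "severe_hypoglycemia": lambda: state("severe_hypoglycemia", bg),
        "severe_hyperglycemia": lambda: state("severe_hyperglycemia", bg),
        "bg_increasing": lambda: trend("bg_increasing", bg),
        "bg_decreasing": lambda: trend("bg_decreasing", bg),
        "bradycardia": lambda: state("bradycardia", hr),
        "tachycardia": lambda: state("tachycardia", hr),
    }
    cache: dict[str, list[Episode]] = {}

    def get(name: str) -> list[Episode]:
        if name not in cache:
            cache[name] = basics[name]()
        return cache[name]

    if night_source == "fitbit":
        nights: Sequence[IntervalAnnotation] = sleeps
    else:
        if bg or hr:
            times = [s.timestamp for s in list(bg) + list(hr)]
            nights = schedule_night_spans(
                profile, min(times).date() - dt.timedelta(days=1), max(times).date()
            )
        else:
            nights = []

    out: dict[str, list[Episode]] = {}
    for name in names:
        if name in basics:
            out[name] = get(name)
        elif name == "rebound_effect":
            out[name] = detect_rebound(
                get("hypoglycemia"), get("hyperglycemia"), rebound_gap, patient_id=pid
            )
        elif name == "dawn_effect":
            out[name] = detect_dawn_effect(
                bg, nights, profile.thresholds, wake_window, min_normal_cover,
                night_source=night_source, patient_id=pid,
                hyper_episodes=get("hyperglycemia"),
            )
        elif name == "tachycardia_precedes_hypoglycemia":
            out[name] = detect_sequence_in_context(
                get("tachycardia"), get("hypoglycemia"), sleeps, sequence_gap,
                pattern=name, patient_id=pid, require_context=sequence_context_required,
            )
        elif name == "hypoglycemia_precedes_bradycardia":
            out[name] = detect_sequence_in_context(
                get("hypoglycemia"), get("bradycardia"), sleeps, sequence_gap,
                pattern=name, patient_id=pid,
            )
    return out
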