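"""Metabolic-control summaries: time in range, episode statistics, nightly
hypoglycemia counts, tag-source comparison, and the ambulatory glucose
profile (AGP).

Every BG sample is weighted by its nominal 15-minute period rather than by
integrating between samples; on the uniform FGM grid the two are equivalent
and the per-sample rule is robust to sensor dropouts. Quantiles use linear
interpolation between order statistics so that tabulated outputs are
bit-for-bit reproducible.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    Channel,
    Episode,
    IntervalAnnotation,
    NOMINAL_PERIOD_MIN,
    PatientProfile,
    Sample,
    Thresholds,
)
from .ta_engine import detect_patterns
from .tagging import schedule_night_spans

MINUTES_PER_DAY = 1440
AGP_PERCENTILES = (10, 25, 50, 75, 90)


@dataclass(frozen=True)
class RangeSummary:
    """Fractions of monitored time in the normal/hyper/hypo glycemic ranges."""

    fraction_normal: Optional[float]
    fraction_hyper: Optional[float]
    fraction_hypo: Optional[float]
    classified_minutes: float

    def __post_init__(self) -> None:
        if self.classified_minutes > 0:
            total = self.fraction_normal + self.fraction_hyper + self.fraction_hypo
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"range fractions must sum to 1, got {total}")


def time_in_range(bg: Sequence[Sample], thresholds: Thresholds) -> RangeSummary:
    """Classify each BG sample (strictly below hypo / strictly above hyper /
    normal) and weight it by one nominal 15-minute period.

    An empty series yields ``classified_minutes=0`` with undefined (``None``)
    fractions.
    """
    if not bg:
        return RangeSummary(None, None, None, 0.0)
    period = NOMINAL_PERIOD_MIN[Channel.BG]
    n = len(bg)
    n_hypo = sum(1 for s in bg if s.value < thresholds.hypo_mgdl)
    n_hyper = sum(1 for s in bg if s.value > thresholds.hyper_mgdl)
    n_normal = n - n_hypo - n_hyper
    return RangeSummary(
        fraction_normal=n_normal / n,
        fraction_hyper=n_hyper / n,
        fraction_hypo=n_hypo / n,
        classified_minutes=float(n * period),
    )


@dataclass(frozen=True)
class EpisodeStats:
    """Per-pattern episode count with median [Q1-Q3] duration in minutes."""

    pattern: str
    count: int
    median_duration: Optional[float] = None
    q1: Optional[float] = None
    q3: Optional[float] = None

    def __post_init__(self) -> None:
        if self.count == 0:
            if any(v is not None for v in (self.median_duration, self.q1, self.q3)):
                raise ValueError("duration fields must be absent when count is 0")
        elif not (self.q1 <= self.median_duration <= self.q3):
            raise ValueError("quartiles must satisfy q1 <= median <= q3")


def episode_stats(episodes: Sequence[Episode]) -> list[EpisodeStats]:
    """Count and duration quartiles per pattern, sorted by pattern name.

    Quartiles are computed with linear interpolation between order
    statistics (the numpy ``linear`` method).
    """
    by_pattern: dict[str, list[float]] = {}
    for ep in episodes:
        by_pattern.setdefault(ep.pattern, []).append(ep.duration_min)
    out = []
    for pattern in sorted(by_pattern):
        durations = np.asarray(by_pattern[pattern], dtype=float)
        q1, med, q3 = np.percentile(durations, [25, 50, 75], method="linear")
        out.append(EpisodeStats(pattern, len(durations), float(med), float(q1), float(q3)))
    return out


def nightly_hypo_table(
    hypo_eps: Sequence[Episode], nights: Sequence[IntervalAnnotation]
) -> tuple[int, int]:
    """(nights with at least one hypoglycemic episode, total nights).

    An episode belongs to a night when the two intervals overlap (closed
    endpoints); a night counts once however many episodes it contains.
    """
    nights_with = 0
    for night in nights:
        if any(ep.start <= night.end and ep.end >= night.start for ep in hypo_eps):
            nights_with += 1
    assert nights_with <= len(nights)
    return nights_with, len(nights)


def tag_context_comparison(
    bg: Sequence[Sample],
    hr: Sequence[Sample],
    sleeps: Sequence[IntervalAnnotation],
    profile: PatientProfile,
    *,
    wake_window: float = 60.0,
    min_normal_cover: float = 0.9,
) -> pd.DataFrame:
    """Nighttime-hypoglycemia and Dawn-Effect counts under the two tag sources.

    The same detections are run twice: once with night/sleep context derived
    from the habit schedule (profile tag) and once from tracked sleep (Fitbit
    tag). With no tracker data the Fitbit column is empty (``NA``) and
    flagged. A nighttime hypoglycemia is a hypo episode that starts inside a
    night span of the given source.
    """
    from .ta_engine import detect_state_episodes, during

    hypo = detect_state_episodes(
        bg, "<", profile.thresholds.hypo_mgdl, pattern="hypoglycemia",
        patient_id=profile.patient_id,
    )
    rows = {}
    for source in ("profile", "fitbit"):
        if source == "fitbit" and not sleeps:
            rows[source] = {"nighttime_hypoglycemia": None, "dawn_effect": None}
            continue
        if source == "fitbit":
            nights: Sequence[IntervalAnnotation] = sleeps
        else:
            times = [s.timestamp for s in bg] or [s.timestamp for s in hr]
            if not times:
                rows[source] = {"nighttime_hypoglycemia": 0, "dawn_effect": 0}
                continue
            nights = schedule_night_spans(
                profile, min(times).date() - dt.timedelta(days=1), max(times).date()
            )
        n_night_hypo = sum(
            1 for ep in hypo if any(during(ep, night, "start_in") for night in nights)
        )
        from .ta_engine import detect_dawn_effect

        dawn = detect_dawn_effect(
            bg, nights, profile.thresholds, wake_window, min_normal_cover,
            night_source=source, patient_id=profile.patient_id,
        )
        rows[source] = {"nighttime_hypoglycemia": n_night_hypo, "dawn_effect": len(dawn)}
    return pd.DataFrame(
        {
            "pattern": ["nighttime_hypoglycemia", "dawn_effect"],
            "profile_tag_count": [rows["profile"]["nighttime_hypoglycemia"], rows["profile"]["dawn_effect"]],
            "fitbit_tag_count": [rows["fitbit"]["nighttime_hypoglycemia"], rows["fitbit"]["dawn_effect"]],
        }
    )


@dataclass(frozen=True)
class AGPCurve:
    """Ambulatory glucose profile: per time-of-day bin BG percentile bands.

    ``bins`` holds the bin start offsets in minutes from midnight;
    ``percentiles`` maps each percentile level to the per-bin values (NaN in
    bins with no data, which are also listed in ``empty_bins``).
    """

    bin_minutes: int
    bins: tuple[int, ...]
    percentiles: dict[int, tuple[float, ...]]
    empty_bins: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        levels = sorted(self.percentiles)
        for i, b in enumerate(self.bins):
            if b in self.empty_bins:
                continue
            vals = [self.percentiles[p][i] for p in levels]
            if any(vals[j] > vals[j + 1] for j in range(len(vals) - 1)):
                raise ValueError(f"percentile curves not ordered in bin {b}")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (bin_start_min, percentile, value)."""
        records = [
            {"bin_start_min": b, "percentile": p, "value": self.percentiles[p][i]}
            for p in sorted(self.percentiles)
            for i, b in enumerate(self.bins)
        ]
        return pd.DataFrame.from_records(records)


def agp(bg: Sequence[Sample], bin_minutes: int = 60) -> AGPCurve:
    """Pool BG samples by time-of-day bin across days and compute the
    10/25/50/75/90 percentile bands.

    ``bin_minutes`` must divide the 1440-minute day. Bins with no samples
    are flagged in ``empty_bins`` and carry NaN values.
    """
    if bin_minutes <= 0 or MINUTES_PER_DAY % bin_minutes:
        raise ValueError(f"bin_minutes must be a positive divisor of 1440, got {bin_minutes}")
    n_bins = MINUTES_PER_DAY // bin_minutes
    pooled: list[list[float]] = [[] for _ in range(n_bins)]
    for s in bg:
        minute = s.timestamp.hour * 60 + s.timestamp.minute
        pooled[minute // bin_minutes].append(s.value)
    curves: dict[int, list[float]] = {p: [] for p in AGP_PERCENTILES}
    empty = []
    for i, values in enumerate(pooled):
        if not values:
            empty.append(i * bin_minutes)
            for p in AGP_PERCENTILES:
                curves[p].append(float("nan"))
            continue
        qs = np.percentile(np.asarray(values, dtype=float), AGP_PERCENTILES, method="linear")
        for p, q in zip(AGP_PERCENTILES, qs):
            curves[p].append(float(q))
    return AGPCurve(
        bin_minutes=bin_minutes,
        bins=tuple(i * bin_minutes for i in range(n_bins)),
        percentiles={p: tuple(v) for p, v in curves.items()},
        empty_bins=tuple(empty),
    )
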