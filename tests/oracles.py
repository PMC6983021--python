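"""Independent brute-force reference implementations used as test oracles.

These deliberately use different mechanics from the library (index scans,
minute enumeration, all-pairs matrices) so that agreement is meaningful.
"""

import datetime as dt
from itertools import groupby


def _min_between(a, b):
    return (b - a).total_seconds() / 60.0


def state_runs(samples, comparator, threshold, max_gap, period):
    """Maximal qualifying runs as (start, end, n, duration) tuples."""
    flags = [
        (s.value < threshold) if comparator == "<" else (s.value > threshold)
        for s in samples
    ]
    runs = []
    idx = 0
    for qualifies, group in groupby(range(len(samples)), key=lambda i: flags[i]):
        block = list(group)
        if not qualifies:
            continue
        # split the block wherever consecutive samples are too far apart
        current = [block[0]]
        for i in block[1:]:
            if _min_between(samples[i - 1].timestamp, samples[i].timestamp) > max_gap:
                runs.append(current)
                current = []
            current.append(i)
        runs.append(current)
    return [
        (
            samples[r[0]].timestamp,
            samples[r[-1]].timestamp,
            len(r),
            _min_between(samples[r[0]].timestamp, samples[r[-1]].timestamp) + period,
        )
        for r in runs
    ]


def trend_runs(samples, direction, min_rate, min_duration, max_gap):
    """Maximal runs of qualifying steps with span >= min_duration."""
    sign = 1 if direction == "increasing" else -1
    step_ok = []
    for i in range(len(samples) - 1):
        spacing = _min_between(samples[i].timestamp, samples[i + 1].timestamp)
        if spacing <= 0 or spacing > max_gap:
            step_ok.append(False)
            continue
        rate = sign * (samples[i + 1].value - samples[i].value) / spacing * 15.0
        step_ok.append(rate >= min_rate)
    out = []
    for qualifies, group in groupby(range(len(step_ok)), key=lambda i: step_ok[i]):
        block = list(group)
        if not qualifies:
            continue
        start, end = samples[block[0]].timestamp, samples[block[-1] + 1].timestamp
        if _min_between(start, end) >= min_duration:
            out.append((start, end, block[-1] + 2 - block[0], _min_between(start, end)))
    return out


def fitbit_tag_scan(t, sleeps, workouts, hr_samples):
    """Tracker tag by scanning every HR sample and every interval."""
    worn = any(
        abs(_min_between(s.timestamp, t)) <= 5.0 for s in hr_samples
    )
    if not worn:
        return "NA"
    for iv in sleeps:
        if iv.start <= t < iv.end:
            return "sleep"
    for iv in workouts:
        if iv.start <= t < iv.end:
            return "workout"
    return "routine"


def profile_tag_by_enumeration(profile, week_start, n_minutes):
    """Profile tags for every minute of a span, nights enumerated minute by
    minute from each bedtime; returns {datetime: tag string}."""
    tags = {}
    end = week_start + dt.timedelta(minutes=n_minutes)
    day = week_start.date() - dt.timedelta(days=1)
    while day <= end.date():
        s = profile.schedule[day.weekday()]

        def clock(t):
            return t.hour * 60 + t.minute

        mid1 = (clock(s.breakfast) + clock(s.lunch)) // 2
        mid2 = (clock(s.lunch) + clock(s.dinner)) // 2
        for m in range(1440):
            t = dt.datetime.combine(day, dt.time(0)) + dt.timedelta(minutes=m)
            if m < clock(s.breakfast):
                tags[t] = "awakening"
            elif m < mid1:
                tags[t] = "after_breakfast"
            elif m < clock(s.lunch):
                tags[t] = "before_lunch"
            elif m < mid2:
                tags[t] = "after_lunch"
            elif m < clock(s.dinner):
                tags[t] = "before_dinner"
            else:
                tags[t] = "after_dinner"
        day += dt.timedelta(days=1)
    # night override: walk each night forward one minute at a time
    day = week_start.date() - dt.timedelta(days=1)
    while day <= end.date():
        s = profile.schedule[day.weekday()]
        t = dt.datetime.combine(day, s.bedtime)
        wake = s.wake
        while t.time() != wake:
            if t in tags:
                tags[t] = "night"
            t += dt.timedelta(minutes=1)
            if _min_between(dt.datetime.combine(day, s.bedtime), t) > 1440:
                break  # degenerate schedule, avoid infinite loop
        day += dt.timedelta(days=1)
    return {
        t: tag
        for t, tag in tags.items()
        if week_start <= t < week_start + dt.timedelta(minutes=n_minutes)
    }


def quantile_sorted(values, p):
    """Linear interpolation between order statistics of the sorted values."""
    xs = sorted(values)
    if len(xs) == 1:
        return xs[0]
    h = (len(xs) - 1) * p / 100.0
    lo = int(h)
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def greedy_pairs_matrix(a_eps, b_eps, accept):
    """Greedy earliest-match pairing from an explicit all-pairs matrix."""
    a_sorted = sorted(a_eps, key=lambda e: (e.start, e.end))
    b_sorted = sorted(b_eps, key=lambda e: (e.start, e.end))
    matrix = [[accept(a, b) for b in b_sorted] for a in a_sorted]
    used = set()
    pairs = []
    for i, a in enumerate(a_sorted):
        for j, b in enumerate(b_sorted):
            if j not in used and matrix[i][j]:
                used.add(j)
                pairs.append((a, b))
                break
    return pairs
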