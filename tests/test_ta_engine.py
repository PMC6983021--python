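import datetime as dt
import random

import pytest
from hypothesis import given, settings, strategies as st

import oracles
from conftest import T0, bg_series, hr_series, make_profile, sleep
from glycta.model import Channel, Direction, Episode, Sample, Thresholds
from glycta.ta_engine import (
    detect_dawn_effect,
    detect_patterns,
    detect_rebound,
    detect_sequence_in_context,
    detect_state_episodes,
    detect_trend_episodes,
    during,
    filter_episodes_by_context,
    precedes,
)
from glycta.tagging import TagPreference, tag_series


def _ep(start_min, end_min, pattern="x", n=2, channel=None):
    return Episode(
        "p", pattern,
        T0 + dt.timedelta(minutes=start_min), T0 + dt.timedelta(minutes=end_min),
        n, float(end_min - start_min), channel,
    )


def random_series(rng, n, channel=Channel.BG, lo=40.0, hi=320.0):
    t = T0
    out = []
    for _ in range(n):
        t += dt.timedelta(minutes=rng.choice([15, 15, 15, 15, 30, 45, 120]))
        out.append(Sample(t, channel, rng.uniform(lo, hi)))
    return out


class TestStateDetection:
    def test_single_severe_sample_forms_15_min_episode(self):
        series = bg_series([55, 48, 52], start=T0.replace(hour=14))
        eps = detect_state_episodes(series, "<", 50)
        assert len(eps) == 1
        ep = eps[0]
        assert ep.start == ep.end == T0.replace(hour=14, minute=15)
        assert ep.duration_min == 15 and ep.n_samples == 1

    def test_constant_series_at_threshold_strict_comparator(self):
        series = bg_series([50] * 8)
        assert detect_state_episodes(series, "<", 50) == []
        assert detect_state_episodes(series, ">", 50) == []

    def test_empty_series_is_not_an_error(self):
        assert detect_state_episodes([], "<", 70) == []

    def test_gap_beyond_max_intra_gap_splits_episode(self):
        series = bg_series([60, 60], step_min=45)
        eps = detect_state_episodes(series, "<", 70, max_intra_gap=30)
        assert len(eps) == 2
        joined = detect_state_episodes(series, "<", 70, max_intra_gap=60)
        assert len(joined) == 1 and joined[0].duration_min == 60

    def test_hr_episode_uses_one_minute_period(self):
        series = hr_series([130, 131], start=T0)
        eps = detect_state_episodes(series, ">", 120)
        assert eps[0].duration_min == 2

    def test_oracle_equivalence_on_random_series(self):
        rng = random.Random(11)
        for _ in range(500):
            series = random_series(rng, rng.randint(0, 120))
            threshold = rng.uniform(50, 280)
            cmp_ = rng.choice(["<", ">"])
            eps = detect_state_episodes(series, cmp_, threshold, max_intra_gap=30)
            got = [(e.start, e.end, e.n_samples, e.duration_min) for e in eps]
            assert got == oracles.state_runs(series, cmp_, threshold, 30, 15)

    def test_maximality_no_adjacent_episodes_can_merge(self):
        rng = random.Random(5)
        for _ in range(100):
            series = random_series(rng, 80)
            eps = detect_state_episodes(series, "<", 150, max_intra_gap=30)
            by_time = {s.timestamp: s for s in series}
            for a, b in zip(eps, eps[1:]):
                assert a.end < b.start
                between = [s for s in series if a.end < s.timestamp < b.start]
                gap_ok = (b.start - a.end).total_seconds() / 60 <= 30
                has_disqualifier = any(s.value >= 150 for s in between)
                assert has_disqualifier or not gap_ok

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(min_value=40, max_value=300), min_size=0, max_size=60),
        threshold=st.floats(min_value=50, max_value=280),
    )
    def test_lowering_hypo_threshold_never_adds_qualifying_samples(self, values, threshold):
        series = bg_series(values)
        n_hi = sum(e.n_samples for e in detect_state_episodes(series, "<", threshold))
        n_lo = sum(e.n_samples for e in detect_state_episodes(series, "<", threshold - 10))
        assert n_lo <= n_hi


class TestTrendDetection:
    def test_steady_rise_of_20_per_15_min(self):
        series = bg_series([100, 120, 140, 160, 180])
        eps = detect_trend_episodes(series, Direction.INCREASING, 15, 35)
        assert len(eps) == 1
        assert eps[0].duration_min == 60 and eps[0].n_samples == 5

    def test_rise_of_12_per_15_min_is_below_rate(self):
        series = bg_series([100, 112, 124, 136])
        assert detect_trend_episodes(series, Direction.INCREASING, 15, 35) == []

    def test_short_steep_ramp_is_below_min_duration(self):
        series = bg_series([100, 130, 160])  # 2 steps, span 30 < 35
        assert detect_trend_episodes(series, Direction.INCREASING, 15, 35) == []

    def test_rate_rescaled_by_actual_spacing(self):
        # +30 over 30 min is exactly 15 per 15 min
        series = bg_series([100, 130, 160, 190], step_min=30)
        eps = detect_trend_episodes(series, Direction.INCREASING, 15, 35, max_intra_gap=30)
        assert len(eps) == 1 and eps[0].duration_min == 90

    def test_decreasing_direction(self):
        series = bg_series([200, 180, 160, 140, 120])
        eps = detect_trend_episodes(series, Direction.DECREASING, 15, 35)
        assert len(eps) == 1 and eps[0].duration_min == 60

    def test_oracle_equivalence_on_random_walks(self):
        rng = random.Random(23)
        for _ in range(500):
            n = rng.randint(0, 100)
            t, v = T0, 150.0
            series = []
            for _ in range(n):
                t += dt.timedelta(minutes=rng.choice([15, 15, 15, 30, 45]))
                v = min(max(v + rng.gauss(0, 22), 40), 400)
                series.append(Sample(t, Channel.BG, v))
            for direction in (Direction.INCREASING, Direction.DECREASING):
                eps = detect_trend_episodes(series, direction, 15, 35, max_intra_gap=30)
                got = [(e.start, e.end, e.n_samples, e.duration_min) for e in eps]
                assert got == oracles.trend_runs(series, direction.value, 15, 35, 30)


class TestTemporalRelations:
    def test_precedes_within_gap(self):
        a, b = _ep(0, 60), _ep(70, 90)
        assert precedes(a, b, 30)

    def test_precedes_gap_exceeded(self):
        a, b = _ep(0, 60), _ep(105, 120)
        assert not precedes(a, b, 30)

    def test_overlapping_episodes_never_precede(self):
        a, b = _ep(0, 60), _ep(30, 90)
        assert not precedes(a, b, 1000)

    def test_during_full_vs_start_in(self):
        container = sleep(T0, T0 + dt.timedelta(hours=8))
        inside = _ep(60, 90)
        straddling = _ep(470, 500)  # ends 20 min after the container
        assert during(inside, container, "full")
        assert not during(straddling, container, "full")
        assert during(straddling, container, "start_in")

    def test_randomized_boundary_agreement_with_brute_force(self):
        rng = random.Random(99)
        for _ in range(1000):
            s0 = rng.randint(0, 500)
            a = _ep(s0, s0 + rng.randint(0, 120))
            c0 = rng.randint(0, 500)
            container = sleep(T0 + dt.timedelta(minutes=c0), T0 + dt.timedelta(minutes=c0 + rng.randint(1, 400)))
            full = container.start <= a.start and a.end <= container.end
            start_in = container.start <= a.start < container.end
            assert during(a, container, "full") == full
            assert during(a, container, "start_in") == start_in


class TestRebound:
    def test_hypo_followed_by_hyper_within_gap(self):
        hypo = [_ep(0, 30, "hypoglycemia")]
        hyper = [_ep(60, 120, "hyperglycemia")]
        eps = detect_rebound(hypo, hyper, 120)
        assert len(eps) == 1
        assert (eps[0].start, eps[0].end) == (hypo[0].start, hyper[0].end)
        assert eps[0].components == (hypo[0], hyper[0])

    def test_no_hyper_episodes_gives_empty(self):
        assert detect_rebound([_ep(0, 30)], [], 120) == []

    def test_each_component_used_at_most_once(self):
        hypo = [_ep(0, 15), _ep(40, 55)]
        hyper = [_ep(70, 100)]
        eps = detect_rebound(hypo, hyper, 120)
        assert len(eps) == 1 and eps[0].start == hypo[0].start

    def test_oracle_equivalence_on_random_streams(self):
        rng = random.Random(31)
        for _ in range(300):
            def stream(k):
                t = 0
                out = []
                for _ in range(k):
                    t += rng.randint(5, 180)
                    out.append(_ep(t, t + rng.randint(5, 90)))
                    t += rng.randint(5, 90)
                return out

            hypo, hyper = stream(rng.randint(0, 6)), stream(rng.randint(0, 6))
            gap = rng.choice([30, 120, 360])
            got = [(e.start, e.end) for e in detect_rebound(hypo, hyper, gap)]
            want = [
                (h.start, H.end)
                for h, H in oracles.greedy_pairs_matrix(hypo, hyper, lambda h, H: precedes(h, H, gap))
            ]
            assert got == want

    def test_wider_gap_never_loses_rebounds(self):
        rng = random.Random(47)
        for _ in range(200):
            hypo = [_ep(t, t + 15) for t in sorted(rng.sample(range(0, 2000, 20), 5))]
            hyper = [_ep(t, t + 30) for t in sorted(rng.sample(range(0, 2000, 20), 5))]
            n30 = len(detect_rebound(hypo, hyper, 30))
            n120 = len(detect_rebound(hypo, hyper, 120))
            n360 = len(detect_rebound(hypo, hyper, 360))
            assert n30 <= n120 <= n360


THR = Thresholds(70, 180, 50, 120)


class TestDawnEffect:
    def _night(self):
        return sleep(dt.datetime(2020, 3, 2, 23), dt.datetime(2020, 3, 3, 7))

    def _normal_night_bg(self):
        return bg_series([110] * 32, start=dt.datetime(2020, 3, 2, 23))  # 23:00-06:45

    def test_normal_night_then_wakeup_hyper(self):
        bg = self._normal_night_bg() + bg_series([260, 265, 250], start=dt.datetime(2020, 3, 3, 7, 20))
        eps = detect_dawn_effect(bg, [self._night()], THR, wake_window=60)
        assert len(eps) == 1
        assert eps[0].start == dt.datetime(2020, 3, 2, 23)
        assert eps[0].end == dt.datetime(2020, 3, 3, 7, 50)

    def test_night_excursion_disqualifies(self):
        bg = self._normal_night_bg() + bg_series([260], start=dt.datetime(2020, 3, 3, 7, 20))
        spiked = [
            Sample(s.timestamp, s.channel, 260.0 if s.timestamp.hour == 2 and s.timestamp.minute == 0 else s.value, s.mode)
            for s in bg
        ]
        assert detect_dawn_effect(spiked, [self._night()], THR) == []

    def test_hyper_outside_wake_window_disqualifies(self):
        bg = self._normal_night_bg() + bg_series([260, 265], start=dt.datetime(2020, 3, 3, 8, 30))
        assert detect_dawn_effect(bg, [self._night()], THR, wake_window=60) == []

    def test_night_without_bg_samples_is_skipped(self):
        bg = bg_series([260, 265], start=dt.datetime(2020, 3, 3, 7, 20))
        assert detect_dawn_effect(bg, [self._night()], THR) == []

    def test_night_source_recorded(self):
        bg = self._normal_night_bg() + bg_series([260], start=dt.datetime(2020, 3, 3, 7, 20))
        eps = detect_dawn_effect(bg, [self._night()], THR, night_source="profile")
        assert eps[0].context_tag == "profile"


class TestSequenceInContext:
    def _sleep(self):
        return sleep(dt.datetime(2020, 3, 2, 23), dt.datetime(2020, 3, 3, 7))

    def _at(self, hhmm_start, hhmm_end, pattern, channel):
        day = dt.datetime(2020, 3, 3)
        s = day + dt.timedelta(hours=hhmm_start[0], minutes=hhmm_start[1])
        e = day + dt.timedelta(hours=hhmm_end[0], minutes=hhmm_end[1])
        return Episode("p", pattern, s, e, 2, (e - s).total_seconds() / 60, channel)

    def test_pair_inside_shared_sleep(self):
        tachy = [self._at((2, 0), (2, 10), "tachycardia", Channel.HR)]
        hypo = [self._at((2, 20), (2, 50), "hypoglycemia", Channel.BG)]
        eps = detect_sequence_in_context(tachy, hypo, [self._sleep()], 30)
        assert len(eps) == 1
        assert (eps[0].start, eps[0].end) == (tachy[0].start, hypo[0].end)
        assert eps[0].context_tag == "sleep"

    def test_second_component_outside_sleep_rejected(self):
        tachy = [self._at((2, 0), (2, 10), "tachycardia", Channel.HR)]
        hypo = [self._at((10, 0), (10, 30), "hypoglycemia", Channel.BG)]
        assert detect_sequence_in_context(tachy, hypo, [self._sleep()], 30, require_context=False) == []
        hypo_near = [self._at((2, 20), (2, 50), "hypoglycemia", Channel.BG)]
        assert detect_sequence_in_context(tachy, hypo_near, [], 30) == []

    def test_context_optional_variant(self):
        tachy = [self._at((10, 0), (10, 10), "tachycardia", Channel.HR)]
        hypo = [self._at((10, 20), (10, 50), "hypoglycemia", Channel.BG)]
        assert detect_sequence_in_context(tachy, hypo, [], 30) == []
        relaxed = detect_sequence_in_context(tachy, hypo, [], 30, require_context=False)
        assert len(relaxed) == 1 and relaxed[0].context_tag is None

    def test_components_share_one_context_interval(self):
        first = sleep(dt.datetime(2020, 3, 3, 0), dt.datetime(2020, 3, 3, 2, 5))
        second = sleep(dt.datetime(2020, 3, 3, 2, 15), dt.datetime(2020, 3, 3, 7))
        tachy = [self._at((2, 0), (2, 4), "tachycardia", Channel.HR)]
        hypo = [self._at((2, 20), (2, 50), "hypoglycemia", Channel.BG)]
        # each component is inside some sleep interval, but not the same one
        assert detect_sequence_in_context(tachy, hypo, [first, second], 30) == []

    def test_oracle_equivalence_on_random_streams(self):
        rng = random.Random(61)
        ctx = [self._sleep()]
        for _ in range(300):
            def stream(k):
                out = []
                for _ in range(k):
                    t = rng.randint(0, 600)
                    out.append(
                        Episode("p", "e", ctx[0].start + dt.timedelta(minutes=t),
                                ctx[0].start + dt.timedelta(minutes=t + rng.randint(1, 60)), 2, 1.0)
                    )
                return out

            a_eps, b_eps = stream(rng.randint(0, 5)), stream(rng.randint(0, 5))
            got = [(e.start, e.end) for e in detect_sequence_in_context(a_eps, b_eps, ctx, 30)]

            def accept(a, b):
                return precedes(a, b, 30) and any(
                    during(a, c, "full") and during(b, c, "full") for c in ctx
                )

            want = [(a.start, b.end) for a, b in oracles.greedy_pairs_matrix(a_eps, b_eps, accept)]
            assert got == want


class TestContextFilter:
    def _setup(self, profile):
        night = sleep(dt.datetime(2020, 3, 2, 23), dt.datetime(2020, 3, 3, 7))
        bg = bg_series([100] * 60, start=dt.datetime(2020, 3, 2, 20))
        hr = hr_series([60] * 900, start=dt.datetime(2020, 3, 2, 20))
        tagged = tag_series(bg, profile, [night], [], hr=hr)
        return tagged

    def test_episode_fully_inside_sleep_kept(self, profile):
        tagged = self._setup(profile)
        ep = Episode("p", "hypoglycemia", dt.datetime(2020, 3, 3, 2), dt.datetime(2020, 3, 3, 3),
                     5, 75.0, Channel.BG)
        kept = filter_episodes_by_context([ep], tagged, "sleep")
        assert len(kept) == 1 and kept[0].context_tag == "sleep"

    def test_straddling_episode_strict_vs_majority(self, profile):
        tagged = self._setup(profile)
        ep = Episode("p", "hypoglycemia", dt.datetime(2020, 3, 3, 6), dt.datetime(2020, 3, 3, 7, 15),
                     6, 90.0, Channel.BG)
        assert filter_episodes_by_context([ep], tagged, "sleep", mode="strict") == []
        kept = filter_episodes_by_context([ep], tagged, "sleep", mode="majority")
        assert len(kept) == 1


class TestDurationConvention:
    def test_minimum_state_duration_is_one_grid_period(self):
        rng = random.Random(77)
        observed = []
        for _ in range(200):
            series = bg_series([rng.uniform(40, 300) for _ in range(60)])
            observed += [e.duration_min for e in detect_state_episodes(series, "<", 70)]
        assert observed and min(observed) == 15

    def test_minimum_trend_span_is_three_grid_steps(self):
        # 3 steps of 15 min is the shortest multiple of the grid >= 35 min
        series = bg_series([100, 120, 140, 160])
        eps = detect_trend_episodes(series, Direction.INCREASING, 15, 35)
        assert len(eps) == 1 and eps[0].duration_min == 45


class TestDetectPatterns:
    def test_unknown_pattern_name_lists_valid_ones(self, profile):
        with pytest.raises(KeyError, match="hypoglycemia"):
            detect_patterns([], [], profile, patterns=["no_such_pattern"])

    def test_runs_all_patterns_on_empty_data(self, profile):
        out = detect_patterns([], [], profile)
        assert set(out) >= {"hypoglycemia", "dawn_effect", "rebound_effect"}
        assert all(v == [] for v in out.values())
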