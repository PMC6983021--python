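# Methods

This note documents the models, conventions and numerical choices behind
`glycta`, and what the synthetic-data experiments do and do not demonstrate.

## Data model and units

All timestamps are naive local clock times at minute resolution. The
patient's day is analysed in local time; no timezone or DST arithmetic is
performed. BG is in mg/dL on a nominal 15-minute grid (the FGM sensor
stores one value per 15 min); HR is in bpm on a nominal 1-minute grid.
Parsers never impute: holes in the input remain holes, and duplicate HR
minutes keep the last value (logged, not silent).

The shipped FGM-export column mapping follows the public FreeStyle-Libre
text layout (a `Record Type` code selecting among automatic BG, scanned BG,
insulin, meal and note rows). Export layouts vary across software versions,
so the mapping is a configurable convention, not a fixed fact about the
format.

## Context tagging

The profile-tag day partition is built only from the times the intake form
collects (meals, bedtime, wake time). With breakfast *B*, lunch *L*, dinner
*D*:

    night           = [bedtime, wake)        — may cross midnight
    awakening       = [wake, B)
    after_breakfast = [B, (B+L)/2)
    before_lunch    = [(B+L)/2, L)
    after_lunch     = [L, (L+D)/2)
    before_dinner   = [(L+D)/2, D)
    after_dinner    = [D, bedtime)

All windows are half-open on the right. A midnight-crossing night is owned
by the bedtime's weekday schedule for its whole span, so one schedule
governs each sleep period. The daytime partition is evaluated by clock
comparison (anything non-night before breakfast is `awakening`, anything
non-night after dinner is `after_dinner`), which keeps the partition total
even when adjacent weekdays declare different wake or bed times. Snack
times are collected but do not create tag values.

The tracker-not-worn rule treats the window [t − 5 min, t + 5 min] as
closed on both ends: an HR sample exactly 5 minutes away counts as
wearing. When a workout is (erroneously) recorded inside a sleep session,
sleep wins, because sleep context is what the multivariate patterns
condition on.

## Episode detection

**State episodes** are maximal runs of consecutive samples strictly beyond
a threshold. Strict comparators mirror the clinical definitions (severe
hypoglycemia is BG < 50 mg/dL, severe hyperglycemia BG > 250 mg/dL; the
per-patient thresholds default to 70/180 mg/dL and 50/120 bpm in the
simulator). A run is also split when consecutive qualifying samples are
more than `max_intra_gap` apart — 30 min for BG (two missed grid samples)
and 5 min for HR by default — so multi-hour sensor dropouts are never
bridged. Episode duration is the sample span **plus one nominal sampling
period**: a single qualifying BG sample is a 15-minute episode. Under a
pure-span convention a one-sample episode would last 0 min, which
contradicts how episode durations are reported clinically (the shortest
reportable excursion is one sensor period).

**Trend episodes** qualify step-by-step: the signed change between
consecutive samples, rescaled to a 15-minute basis by the actual spacing,
must be ≥ 15 mg/dL (or ≤ −15 for decreasing), with spacing ≤
`max_intra_gap`. Episodes are maximal runs of qualifying steps with
first-to-last span ≥ 35 min; duration is the pure span. On the 15-minute
grid the shortest trend episode is therefore 3 steps = 45 min, and the
shortest state episode 15 min — both verified structurally in the test
suite and the acceptance script.

**Temporal relations.** `precedes(a, b, gap)` holds iff `a.end ≤ b.start`
and the separation is at most `gap` minutes. `during(a, c)` supports full
containment (default for the sleep-context patterns, since both component
events are understood to occur within sleep) and a `start_in` variant.

**Complex patterns** pair component episodes greedily, earliest first, each
component participating in at most one pair — deterministic and
order-independent. Defaults, all config-exposed because no clinical
standard fixes them: rebound gap 120 min; tachycardia→hypoglycemia and
hypoglycemia→bradycardia gap 30 min; Dawn-Effect wake window 60 min. The
sleep context of Tachycardia PRECEDES Hypoglycemia is optional via
`require_context` (default on).

**Dawn Effect.** A night qualifies when the BG samples inside the night
interval are normal — at least `min_normal_cover` (default 0.9) of them in
[hypo, hyper] and none strictly beyond either threshold — and a
hyperglycemia episode starts within the wake window after the night ends.
Note that under strict thresholds the no-breach condition implies full
coverage, so the cover parameter only becomes active if the breach
condition is relaxed in a custom analysis; both are kept for
configurability. Night spans come from tracked sleep by default, or from
the schedule (`night_source="profile"`), and every emitted episode records
which source produced it; nights without BG samples are skipped and logged.

## Summaries

Time in range weighs every BG sample by one nominal 15-minute period
instead of integrating between samples; on the uniform grid the two
coincide, and the per-sample rule degrades gracefully across dropouts.
Quantiles (episode-duration quartiles, AGP bands) use linear interpolation
between order statistics — numpy's `linear` method — so tabulated outputs
are bit-for-bit reproducible. The AGP pools samples by time-of-day bin
across days (default 60-minute bins; any divisor of 1440 is accepted) and
reports the 10/25/50/75/90 percentile bands. A night counts toward the
nightly-hypoglycemia table when an episode *overlaps* it (closed
endpoints); containment was the alternative reading, and overlap was chosen
so that an episode straddling wake-up still counts against the night it
began in.

## Synthetic cohorts

The generator emulates the two device streams and the patient config,
emitting the exact file dialects the parsers read plus a ground-truth
manifest.

* BG baseline: mean-reverting AR(1) on the 15-min grid (mean 120 mg/dL,
  stationary s.d. 15, lag-1 autocorrelation 0.8) — the simplest process
  with realistic autocorrelation — plus white measurement noise
  (s.d. 2 mg/dL) on every stored value.
* HR baseline: context-dependent means (sleep 60, routine 72, workout
  105 bpm, s.d. 2) driven by the generated sleep/workout sessions.
* Sleep: bedtime 23:00, wake 07:00, both displaced per night by
  `N(shift_mean, 15 min)`; a non-zero mean simulates an irregular sleeper
  whose tracked nights diverge from the declared schedule.
* Plants **overwrite** the baseline rather than adding to it, so the
  manifest is valid by construction. State plants sit one margin
  (default 20 mg/dL / 15 bpm) beyond the threshold; trend plants are exact
  ±20 mg/dL-per-15-min ramps inside the normal range; complex plants are
  laid out on separate days/nights, anchored to the tracked sleep
  intervals, with spacings chosen so no unplanned pairing can arise. The
  default layout needs a 6-day span; shorter spans with plants enabled are
  rejected.
* Dropout blocks (expected 0.25/day, 120 min) delete both BG and HR
  samples and are drawn to never overlap a planted window.

With all noise off, every detector recovers exactly the planted set
(precision = recall = 1); with 5 mg/dL sensor noise against the 20 mg/dL
margins, planted glycemic state episodes are recovered with recall ≥ 0.95
across 100 seeds. The acceptance script measures both.

**What passing does not show.** The generator produces piecewise-stationary
glycemia with idealised excursions: no meal absorption or insulin kinetics,
no circadian BG rhythm, no scanned (off-grid) readings, no tracker
sleep-staging errors. Recovery results therefore validate the detection
logic and its conventions, not performance on physiologic waveforms, where
excursions are slower-shouldered and thresholds are crossed gradually.

## Problem sizes and determinism

Every random draw flows from a single integer seed
(`numpy.random.default_rng([seed, patient_index])`), so cohorts,
detections, and CLI outputs are byte-reproducible. The shipped experiments
use desk-scale sizes — cohorts of 1–3 patients over 7 days, 100 seeds for
the noisy-recall estimate, 300–500 random series for the oracle-equivalence
checks — which keep the full test suite under ten seconds while exercising
every code path; the sizes are set in the tests and the acceptance script
and scale up directly.

## Known limitations

* The profile-tag partition midpoints are a declared convention; the form
  data does not determine where "after breakfast" ends.
* Trend detection under measurement noise is fragile near the exact rate
  threshold (a 15 mg/dL criterion on a noisy 20 mg/dL step flips easily);
  only state-episode recovery is claimed under noise.
* Episode context filtering inspects samples on the episode's own channel
  within its span; an episode whose span contains no tagged samples is
  dropped rather than guessed.
* The CLI processes one patient per invocation; cohort-level iteration is
  left to shell loops or the library API.
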