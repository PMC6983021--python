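# glycta

Temporal-abstraction analytics for flash glucose monitoring (FGM) integrated
with activity-tracker data.

Children and adolescents with type 1 diabetes increasingly wear two devices
at once: an FGM sensor that stores one blood-glucose (BG) value every 15
minutes, and a wrist tracker that records heart rate (HR) once per minute
along with sleep and workout sessions. Sleep and physical activity alter
glucose metabolism for hours, so clinically meaningful questions are joint
ones — *does this patient go hypoglycemic during sleep? does a normal night
end in morning hyperglycemia?* — that neither device answers alone.
`glycta` is a library + CLI for clinicians' analysts and digital-health
researchers that ingests both data streams, places every measurement in the
context of the patient's day, and extracts interpretable episodes and
summaries from the combined series.

## Method

The analytic core is **temporal abstraction**: converting numeric time
series into labeled intervals, then composing intervals with temporal
relations.

**Context tagging.** Every BG/HR sample gets two labels. The *profile tag*
partitions the day using the patient's declared habit schedule (`night`
between bedtime and wake time, then `awakening`, `after_breakfast`,
`before_lunch`, `after_lunch`, `before_dinner`, `after_dinner`). The
*Fitbit tag* is `sleep`/`workout`/`routine` from tracked sessions, or `NA`
when the tracker was not worn — declared when no HR sample exists within
±5 min of the event. Analyses can prefer the tracker tag and fall back on
the profile tag (`fitbit_first`), or use the schedule alone
(`profile_only`).

**Episodes.** With patient-specific thresholds *hypo*, *hyper*, *brady*,
*tachy*:

- *state abstraction* — maximal runs of consecutive samples with
  `BG < hypo`, `BG > hyper`, `HR < brady` or `HR > tachy` (strict
  comparators; severe excursions use BG < 50 and BG > 250 mg/dL). A run
  lasts its sample span plus one nominal sampling period, so a single
  qualifying BG sample is a 15-minute episode;
- *trend abstraction* — BG Increasing / Decreasing: maximal runs of steps
  changing by ≥ 15 mg/dL per 15 min (rescaled by actual spacing),
  sustained for ≥ 35 min;
- *complex patterns* via the interval relations `PRECEDES` (within a
  maximum gap) and `DURING` (containment): Rebound Effect (hypo followed by
  hyper), Dawn Effect (normal BG all night, hyperglycemia at wake-up),
  Tachycardia PRECEDES Hypoglycemia during sleep, and Hypoglycemia PRECEDES
  Bradycardia during sleep.

**Summaries.** Time in normal/hyper/hypo range, per-pattern episode counts
with median [IQR] durations, nights with at least one hypoglycemic episode,
side-by-side pattern counts under schedule-derived vs tracker-derived night
context, and the ambulatory glucose profile (AGP: per-time-of-day-bin
10/25/50/75/90 BG percentile bands pooled across days).

Because raw patient exports are rarely shareable, the package ships a
seed-reproducible synthetic cohort generator that emits the exact input
dialects the parsers read (FGM-reader TSV, tracker JSON, patient YAML) with
a ground-truth manifest of every injected pattern occurrence.

## Worked example

```python
from glycta import (ScenarioConfig, simulate_patient, detect_patterns,
                    time_in_range, episode_stats)

cfg = ScenarioConfig(seed=7, n_patients=1)          # one simulated week
bundle = simulate_patient(cfg, 0)
detected = detect_patterns(bundle.bg, bundle.hr, bundle.profile, bundle.sleeps)
episodes = [ep for eps in detected.values() for ep in eps]

tir = time_in_range(bundle.bg, bundle.profile.thresholds)
print(f"time in range: normal={tir.fraction_normal:.3f} "
      f"hyper={tir.fraction_hyper:.3f} hypo={tir.fraction_hypo:.3f}")
for st in episode_stats(episodes):
    print(f"{st.pattern:35s} n={st.count:3d} median={st.median_duration:6.1f} min "
          f"[{st.q1:.1f}-{st.q3:.1f}]")
```

prints

```
time in range: normal=0.973 hyper=0.013 hypo=0.013
bg_decreasing                       n=  1 median=  60.0 min [60.0-60.0]
bg_increasing                       n=  1 median=  60.0 min [60.0-60.0]
bradycardia                         n=  2 median=  10.0 min [10.0-10.0]
dawn_effect                         n=  1 median= 539.0 min [539.0-539.0]
hyperglycemia                       n=  3 median=  45.0 min [45.0-45.0]
hypoglycemia                        n=  5 median=  30.0 min [30.0-30.0]
hypoglycemia_precedes_bradycardia   n=  1 median=  42.0 min [42.0-42.0]
rebound_effect                      n=  1 median= 150.0 min [150.0-150.0]
severe_hypoglycemia                 n=  4 median=  15.0 min [15.0-18.8]
tachycardia                         n=  2 median=  10.0 min [10.0-10.0]
tachycardia_precedes_hypoglycemia   n=  1 median=  49.0 min [49.0-49.0]
```

The patient spends 97.3% of monitored time in range. Each planted pattern
occurrence is recovered (the extra hypoglycemia and the severe episodes come
from the simulated sensor noise around the planted excursions, which sit at
50 mg/dL). The 539-minute Dawn Effect episode spans the whole normal night
plus the morning hyperglycemia; its duration is dominated by the night.

The same pipeline runs from the shell:

```bash
glycta simulate --out cohort --seed 42 --patients 1
glycta ingest --libre cohort/sim000/libre.tsv --hr cohort/sim000/hr.json \
              --sleep cohort/sim000/sleep.json --workouts cohort/sim000/workouts.json \
              --out dataset
glycta tag       --dataset dataset --config cohort/sim000/patient.yaml --out tagged.csv
glycta detect    --dataset dataset --config cohort/sim000/patient.yaml --out episodes.csv
glycta summarize --dataset dataset --config cohort/sim000/patient.yaml \
                 --episodes episodes.csv --out summaries
```

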