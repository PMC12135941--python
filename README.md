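# damsleep

Sleep quantification for *Drosophila* activity-monitor data: beam-break
sleep scoring, multibeam behavior classification with validation
statistics, sleep-deprivation rebound bookkeeping, arousal-threshold
curves, and courtship-memory statistics — plus a seeded synthetic
activity generator with exported ground truth so the whole pipeline is
testable without raw monitor files.

## Who this is for

Sleep and circadian labs that record flies in Trikinetics-style activity
monitors (single-beam DAM2 or 15-beam DAM5H tubes) and need a scripted,
reproducible path from raw tab-separated monitor files to the per-fly
metrics that appear in sleep papers: total sleep, day/night bout
architecture, waking activity, percent sleep change under neuronal
activation, percent of lost sleep recovered after deprivation, arousal
dose-response curves, and courtship suppression indices.

## The core definitions

* **Sleep.** Activity is binned per minute. A minute is *quiescent* when it
  has zero beam-break counts (single-beam), or zero within-beam counts and
  zero cross-beam moves (multibeam). A **sleep bout** is any maximal run of
  quiescent minutes with length ≥ 5; total sleep is the summed bout length.
  Day metrics cover ZT0–ZT12 (lights on), night ZT12–ZT24, in a 12:12 LD
  cycle. Waking activity = total counts during awake minutes / number of
  awake minutes.
* **Multibeam behavior classes.** Per minute: any `moves` → *walking*;
  `counts` but no `moves` → *micromovement* (feeding, grooming, posture
  change, proboscis extension, single-leg movement); neither → *rest*.
  Against per-minute video labels, `sensitivity(b) = minutes of behavior b
  the monitor identified / all labeled minutes of b` and `accuracy(c) =
  correctly identified minutes of class c / all minutes the monitor
  assigned to c`.
* **Homeostasis.** Sleep lost = baseline sleep − deprivation-day sleep over
  the 12-h deprivation window; the gain curve is the running sum of
  (recovery − baseline) sleep over time-of-day-matched minutes; percent
  recovered at h hours = 100 × gain(h) / lost.
* **Arousal threshold.** A fly inactive for the full 5 min before stimulus
  onset is *sleeping*; the curve reports the percent of sleeping flies
  whose first movement occurred at or below each intensity of an
  escalating 20 %→100 % ladder.
* **Courtship memory.** CI = 100 × courting time / test duration over a
  10-min test; CIs < 10 % are excluded from both groups;
  SI = 100 × (1 − CI_trained / CI_untrained) with the untrained group mean
  as the denominator.

## Worked example

```python
import numpy as np
from damsleep import SimConfig, simulate_fly, LightSchedule
from damsleep.sleep import quiescence, detect_sleep_bouts, sleep_metrics

cfg = SimConfig(seed=1)                      # two-state sleep/wake fly
series, truth = simulate_fly(cfg, n_days=2)  # 2880 one-minute bins
bouts = detect_sleep_bouts(quiescence(series, "multibeam"))
m = sleep_metrics(series, bouts, LightSchedule(), window=(0, 1440))
print(m.total_sleep_min, m.day_sleep_min, m.night_sleep_min)
print(round(m.waking_activity, 2))
```

prints

```
818 394 424
2.01
```

818 minutes of scored sleep on day 1, split 394 (light phase) / 424 (dark
phase) — night-heavy, as the circadian modulation intends — and 2.01
activity counts per awake minute, a normal locomotor level (a near-zero
value would suggest a moribund fly rather than a sleepy one).

The same objects drive every other analysis, e.g. classification and
validation:

```python
from damsleep.multibeam import classify_minutes, validate
report = validate(classify_minutes(series), truth.behavior)
print(report.combined_walk_micro_sensitivity_pct)  # e.g. 100.0
```

A command-line layer mirrors the library (`damsleep ingest | simulate |
score | classify-mb | validate-mb | rebound | arousal | courtship | run`);
`damsleep run config.yaml` executes a declarative ingest→QC→score→analysis
pipeline and writes a manifest that reproduces the run.

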