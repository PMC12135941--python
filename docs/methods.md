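# Methods

This note documents the scoring rules, the synthetic-data model, numerical
conventions, and the design choices made where more than one reasonable
convention exists.

## Sleep scoring

Activity is analyzed in 1-min bins, 0-based half-open minute intervals
everywhere. A minute is quiescent when `counts == 0` (single-beam) or
`counts == 0 and moves == 0` (multibeam: in-place micromovements break
quiescence). Sleep bouts are maximal quiescent runs of length ≥ 5 min.
Conventions:

* **Edge bouts** touching the start or end of the analysis window count
  when their observed length meets the threshold. This preserves
  minute-count conservation (sleep + wake = window length) at the cost of
  occasionally truncating a bout that extends beyond the recording.
* **Boundary-spanning bouts.** Day (ZT0–ZT12) and night (ZT12–ZT24) bout
  statistics are computed by default on bout *fragments* truncated at ZT
  boundaries; each fragment counts toward its own period even when shorter
  than 5 min, because the parent bout met the threshold. This conserves
  sleep minutes across periods. `split_boundary_bouts=False` instead
  attributes a spanning bout wholly to the period containing its first
  minute; whole-day totals are identical either way.
* **Percent sleep change** between a baseline and a test day is
  100 × (test − baseline)/baseline. A zero-baseline fly has no defined
  value and is excluded with a logged reason rather than propagating an
  infinity into cohort statistics.
* **Viability QC**: a fly with fewer than `min_counts` (default 1) total
  counts over its final `tail_hours` (default 6) is flagged as dead.
  These defaults are pragmatic conventions, exposed in configuration.

## Raw-file ingestion

Monitor files are tab-separated rows (index, date, time, status code,
metadata columns, then one value per channel). Firmware variants differ,
so column offsets and the channel→fly assignment are configured through a
`ChannelMap` rather than hard-coded. Readings are summed into whole
minutes of the monitor clock; partial leading/trailing minutes are dropped
(logged). Missing or error-status readings contribute zero activity but
lower the bin's completeness fraction; bins below 50 % completeness are
flagged so a dead channel is distinguishable from a quiescent fly.
Multibeam `position` takes the last valid reading in each bin, carried
forward over empty bins, and must lie in 1..15 (the tube has 15 beams).

The canonical interchange format is a long CSV (`fly_id, minute_index,
iso_time, counts, moves, position, light, led, completeness`) plus a JSON
sidecar with the schema version and per-fly metadata. It round-trips all
fields losslessly and is byte-stable under fixed field ordering, so runs
can be diffed.

## Multibeam classification and validation

The minute hierarchy (moves → walking; counts only → micromovement;
neither → rest) is validated against per-minute video labels built from
interval annotations by highest activity level: any walking labels the
minute walking; otherwise the micromovement behavior with the longest
cumulative duration wins, ties broken by the fixed order feeding >
grooming > posture_change > proboscis_extension > single_leg_movement.
The tie-break is a declared convention chosen for determinism; a minute
containing two different micromovements has no canonical label otherwise.

Derived statistics: the combined walking/micromovement sensitivity
collapses every movement class into one activity class on both sides
(walking minutes scored as micromovements are detected activity, not false
rest); the sleep-inclusive rest accuracy remaps posture change, proboscis
extension and single-leg movement — behaviors that occur within sleep — to
rest before computing rest accuracy; false sleep episodes are
predicted-rest runs ≥ 5 min that contain at least one real feeding or
grooming minute. Report percentages are rounded to one decimal, half-up.

## Homeostasis

Sleep lost is baseline-window sleep minus deprivation-window sleep over
matched 12-h windows (by default the dark phase of the deprivation day and
the same clock window one day earlier), clamped at 0 with a warning when a
fly slept more during deprivation — negative losses are not meaningful
inputs to a recovery ratio. The gain curve retains negative excursions
(sleep lost then gained is a continuous bookkeeping quantity). Gain at
checkpoint h is read at the last minute of hour h. Recovery minutes are
matched to the baseline day by time-of-day, so recovery spans longer than
24 h reuse the single baseline day cyclically. Flies with lost <
`min_lost` (default 60 min) get `valid=False` and no percentages: a
recovery ratio over a near-zero denominator is numerically meaningless.
The threshold is a declared convention, surfaced in configuration and
logs.

## Arousal threshold

One stimulus step is 4 × (200 ms on + 800 ms off) followed by a 15-s
break; intensities rise 20 % → 100 % in 20 % increments. A fly inactive
for the full 5 min before onset is sleeping; others are ignored entirely.
The default curve is cumulative — percent of sleeping flies whose first
movement occurred at or below each intensity — which is monotone
non-decreasing and matches dose-response curves that rise toward 100 % at
the strongest stimulus. A per-step hazard mode (fraction of still-asleep
flies awakened at each step) is available behind a flag. Movement during
a step's trailing break attributes to that step by default, since manual
video scoring imposes no fixed response latency; the window is
configurable.

## Courtship

CI merges overlapping courting intervals before summing. The SI
denominator uses the *group mean* untrained CI for both the group SI and
per-fly SIs: trained and untrained flies are distinct individuals, so no
per-fly pairing exists, and the shared denominator makes
mean(per-fly SI) = group SI exactly. Exclusion of CIs < 10 % applies to
both groups, is order-independent and idempotent.

## Synthetic-data model

The generator works at minute resolution because every analysis does;
sub-minute structure exists only as LED duty fractions and Poisson count
rates. Latent dynamics are a two-state Markov chain with per-minute
wake→sleep probability

    p_ws(t) = clip( p_ws · circadian_gain^[dark] · led_effect^[duty>0]
                    · (1 + pressure(t)), 0, 1 )

and constant sleep→wake probability `p_sw`. Multiplicative composition
keeps the modifiers independent and the probability bounded after
clipping (clipping is logged). Defaults: `p_ws = p_sw = 0.05` (mean sleep
and wake bout scale of 20 min), `circadian_gain = 2` (night sleep
fraction 2/3 vs 1/2 by day — a night-heavy sleeper), `lambda_moves = 1`
and `lambda_counts = 2` per awake minute (normal locomotion),
`p_sleep_micro = 0.02` (occasional posture-change-like single counts
during sleep), `rebound_gain = 0.003` and `rebound_decay = 0.998`
(pressure built over a 12-h forced waking roughly doubles the sleep drive
at recovery onset and decays with a ~6-h half-life). These are plausible
fly-like values chosen once; they are the fixed study conditions for all
tests.

Emissions use the classifier's own vocabulary, which makes ground truth
exact: awake minutes draw moves and counts from independent Poissons and
are labeled walking / a micromovement behavior / rest accordingly;
sleeping minutes are silent except for the posture-change emission.
Forced-wake minutes during deprivation always emit at least one count
(the mechanical device keeps the fly moving), so scored sleep during the
deprivation window is exactly zero. LED duty fractions per protocol:
1 Hz = 5/1000, regular = (20×5 ms)/(20×100 ms + 4 s) ≈ 0.0167,
10 Hz = 5/100, 20 Hz = 5/50, 50 Hz = 5/20, constant = 1.

Per-fly seeds are a stable 32-bit hash of (master seed, fly id), so
cohorts are bit-reproducible and insensitive to insertion order.

What the generator does *not* emulate: inter-fly parameter heterogeneity,
ultradian structure, light-transition anticipation, position-dependent
beam sensitivity, and any mechanistic circuit model. Tests passing on
synthetic data therefore demonstrate correctness of the scoring
machinery under the stated statistical structure, not fidelity of any
particular biological effect size.

## Problem sizes and statistical checks

Property suites compare each scoring primitive against an independent
brute-force implementation on 10⁴ randomized small instances. The
stationary-limit check uses 20 flies × 10 days with flat circadian gain
and compares the latent sleep fraction to p_ws/(p_ws+p_sw) within 3
standard errors across flies. Effect-recovery checks use 50
flies/condition over 2 days (activation ordering) and 100 flies over 4
days (rebound), with the no-rebound null assessed by a 99 % bootstrap
percentile CI (2000 resamples) covering zero. These sizes give stable
verdicts under the fixed seeds while keeping the default suite quick.

## Known limitations

* Light state is derived from a declared 12:12 schedule, not from a light
  sensor channel.
* The video-label precedence and micromovement tie-break are conventions;
  annotated datasets with a different labeling policy should be converted
  upstream.
* The arousal module consumes per-fly movement events; it does not score
  video.
* Group hypothesis testing (ANOVA, post-hocs, signed-rank tests) is
  delegated to standard statistics packages and not reimplemented here.
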