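# Methods

This note documents the models behind `uemasim`, the defaults and why
they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions used throughout.

## Prompt scheduling

Prompts are signal-contingent: device-initiated at pseudo-random times,
four per clock hour. Each hour is generated independently with the
recurrence

    P_n = U[0, MaxTimeAvailable_n) + 8 + P_{n−1},  P_0 = 0,  n = 1..4
    MaxTimeAvailable_n = 55 − ((4 − n + 1) × 8) − P_{n−1}

`MaxTimeAvailable_1 = 23 > 0`, and each draw leaves exactly enough room
for the remaining prompts, so the recurrence is always feasible: four
offsets in [8, 55) with consecutive gaps ≥ 8 min. Because an hour's
last prompt is below minute 55 and the next hour's first is at or after
minute 68, the cross-hour gap is structurally ≥ 13 min. Draws are
continuous uniforms (the recurrence does not fix a resolution; we store
times at 1-second resolution). The full 24-hour schedule is generated
and then clipped to the waking window, so days whose window is not
hour-aligned can have fewer (or, at the edges, more) than the nominal
62 prompts; daily totals are reported as realized, not forced. The
schedule is regenerated at the start of each day.

Waking window: prompting runs from 15 min after wake to 15 min before
sleep, defaults 07:00 wake / 23:00 sleep (a 16-h waking day, 15.5-h
prompting span, 62 nominal opportunities). Days without a sleep/wake
report reuse the previous day's window, modelled as calendar overrides
carried forward. Do-not-disturb intervals mark prompts
scheduled-but-not-delivered; off-wrist and charging leave prompting
untouched. A degenerate window yields an empty schedule and a warning.

Calendar: 4-day measurement bursts containing Saturday and Sunday every
14 days (so ≥ 7 clear days between bursts), at most 26 per study;
the default block is Friday–Monday (any anchor whose 4-day block
contains the weekend is accepted). A 365-day study gives 26 bursts,
104 burst days, and 261 watch-EMA days. All randomness flows from a
single `numpy` `SeedSequence` hierarchy (per-participant, per-day
substreams); identical seed + config reproduce schedules bit-for-bit.

## Question selection

Daily slot quotas: validation = round(2% of scheduled prompts), minimum
1; engagement = round(8%), minimum 1 once ≥ 2 prompts exist; core =
the nominal 90% (floor); any remainder folds into core, the nominal
majority class — at 62 prompts this gives 55 core + 5 engagement +
1 validation + 1 spare → 56 core slots in the live protocol. Classes
are randomly interleaved over the day's slots.

Core selection draws uniformly from the day-level subset (4 internal,
2 external, 2 reflective, 2 reactive out of 13/6/6/5) after removing
items at their per-day answered cap and items answered within the last
60 minutes. Only *answered* presentations advance the cap counter and
re-ask clock — a missed or dismissed item may legitimately repeat at
the very next prompt, so consecutive non-repetition is guaranteed only
for answered items. If every subset item is filtered out (rare: all
capped or all inside the re-ask gap), the prompt presents the next
engagement item rather than going empty.

Per-item caps are configuration; the defaults are 8/day for internal
items (fast-moving affective states), 4/day for external, reflective
and reactive items, and 1/day for the once-daily sleep-quality item.
These defaults give a 10-item subset a daily answered capacity of ~49–56
against ~41 expected answered core prompts at 75% answering, which is
what produces the observed median of 4 answered repetitions per
presented day. Engagement (280 items) and validation (300 items) banks
are consumed via a shuffled-once sequential cursor, giving multi-month
no-repeat horizons proportional to bank size.

## Sensor triggering

Activity intensity is the AUC of the high-pass-filtered tri-axial
signal per 10-s epoch: Σ over samples and axes of |filtered value| ×
(1/50 s), a rectangle rule (indistinguishable from a trapezoid at
50 Hz). The filter is a first-order Butterworth at 0.25 Hz applied
forward–backward per axis — the family and cutoff are design choices:
they remove gravity and slow posture drift while passing the human
movement band, and both are exposed in configuration.

Bout rules: PA = ≥ 60 consecutive epochs (10 min) above threshold;
SB = ≥ 360 consecutive epochs (60 min) below threshold; maximal runs
are reported. The default thresholds (2.67 g·s per epoch, both kinds)
were calibrated once as the midpoint between the sedentary and active
per-epoch AUC distributions of the bundled generator at its default
intensities (≈ 0.24 vs ≈ 5.1 g·s), and can be re-derived for other
data with `calibrate_thresholds`. Requiring the SB threshold ≤ the PA
threshold makes emitted PA and SB bouts provably non-overlapping.

A triggered question refers back Δ = (now − bout end) + 25% of bout
length (2.5 min for a 10-min PA bout at its end; 15 min for a 60-min SB
bout), aiming inside the behaviour rather than at its transition. At a
scheduled prompt an eligible bout preempts the queued question with
probability 0.5; a bout stays eligible until prompted about or
superseded by a newer bout of its kind; on an exact tie of end times PA
wins (logged; the choice is arbitrary but fixed).

The synthetic accelerometer emulates only what detection needs:
labelled intervals whose epoch-AUC distributions separate cleanly
(white movement noise of scripted intensity plus gravity and, for
active intervals, a 1.8-Hz arm-swing harmonic). It does not emulate
real wrist nonstationarity, orientation changes, device artefacts or
intensity overlap between behaviours, so passing recovery tests shows
the detector implements its rules correctly — not that the default
thresholds would hold on field data, where they are explicitly
empirical quantities.

## Respondent model

A delivered prompt is answered with probability `answer_prob` (default
0.75). Conditional on an initial answer: undo is pressed with
probability 0.05, after which the answer is abandoned with probability
0.10 (partially completed); without an undo the acknowledgment screen
is swiped away with probability 0.02 (completed then dismissed).
Unanswered prompts are swiped (never started) with probability 0.02,
else they time out (missed). Latencies are log-normal (mean ≈ 4.8 s,
SD ≈ 1.4 s) truncated to the 20-s display window — a plausibility
default for simulated logs, deliberately not a quantity any test
asserts against observed cohort values. Answer content for core items
is uniform over the option set; validation items are answered correctly
with probability 1 − `validation_error_rate` (default 0.93 correct).
None of this models real psychological dynamics; the profile is a
stationary parameter vector, and an extension hook for
context-dependent compliance is the natural next step.

## Metrics

Compliance = answered/scheduled × 100 (scheduled includes
DND-suppressed prompts), completion = answered/delivered × 100, undo =
undos/answered × 100, validation = correct/answered validation × 100.
"Answered" means final status `answered`; a prompt abandoned after an
undo does not count. Zero denominators yield *undefined* (None) rates,
never zero, with the affected rate names flagged. Day- and
participant-level summaries are unweighted means of per-unit rates;
with denominator weighting they reduce exactly to the pooled ratio
(consistency identity, tested). Presentation statistics count
*answered* presentations: a question's day-coverage is the fraction of
logged participant-days with ≥ 1 answered presentation, and its
repetition measure is the median answered count over those days.

## Sampling simulation

The selection-strategy experiment simulates 300 users × 261 watch-EMA
days (78,300 days; a 50-user desk-scale run is the testing default,
and 5-user runs are used in unit tests). Time is abstracted to a slot
sequence: 62 slots at 15-minute spacing (15.5 h / 62), of which 55
randomly positioned slots are core — matching the design accounting
that reserves 55 daily slots for core items — with the 60-minute
re-ask filter acting over slot times, i.e. ~4 slots. Each slot is
answered with probability 0.75. Random mode draws every core slot
uniformly from the 30-item bank with no filters; filtered mode runs
the day-subset/cap/re-ask pipeline.

The analytic anchor for random mode: with A ≈ 0.75 × 55 = 41 answered
core slots, a given item is missed all day with probability (29/30)^41,
so expected day-coverage is 1 − (29/30)^41 ≈ 75.1%; the simulation
agrees within Monte-Carlo error. Filtered-mode coverage is the
category-inclusion probability (4/13 for internal, 2/6, 2/6, 2/5
elsewhere; bank-weighted average exactly 1/3), since a subset item is
almost surely answered at least once. Medians: 2 repetitions per
presented day under random selection vs 4 under filtering — the design
argument for filtering, since within-day slope estimation needs ≥ 3
observations.

## Known limitations

- Single time zone, no clock changes; dates are naive local time.
- Sleep windows must lie within one calendar day (no past-midnight
  sleep times); such schedules degenerate to empty days rather than
  wrapping.
- The respondent and accelerometer generators are deliberately simple
  (see above); simulated compliance says nothing about real cohorts.
- Burst placement is deterministic given the anchor weekday; the
  protocol's dependency of watch-day counts on smartwatch shipping
  dates is reduced to a configurable pre-study lead-in.
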