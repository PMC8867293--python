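# uemasim

Simulator and analysis library for **microinteraction ecological
momentary assessment (μEMA)** study protocols — the smartwatch variant
of EMA in which every prompt is a single, cognitively simple question
answered with one glance-and-tap (e.g. *Feeling stressed?* — Yes /
Sort of / No), asked four times an hour across a year-long study.

The package is aimed at study designers and methodologists who want to
stress-test a μEMA protocol — prompt density, question-selection rules,
per-item caps, sensor triggering, expected compliance accounting —
before fielding it, and at analysts who need the standard
response-behaviour metrics from μEMA event logs.

## What it models

**Prompt scheduling.** Within each clock hour the *n*-th prompt offset
(minutes past the hour) follows

    P_n = U[0, MaxTimeAvailable_n) + 8 + P_{n−1},   P_0 = 0
    MaxTimeAvailable_n = 55 − ((4 − n + 1) × 8) − P_{n−1}

which guarantees exactly 4 prompts per hour, all offsets in [8, 55)
minutes, and at least 8 minutes between consecutive prompts. The 24-h
schedule is clipped to the participant's waking window (15 min after
wake to 15 min before sleep); do-not-disturb suppresses delivery but
not scheduling. A year-long calendar alternates 4-day smartphone-EMA
bursts (every 2 weeks, always containing Saturday and Sunday, at most
26 per year → 104 burst days) with up to 261 watch-EMA days.

**Question selection.** Of the nominal 62 daily prompts, 55 go to
core-construct items, 5 to engagement items and 1 to a validation
(attention-check) item. Core prompts draw from a *day-level subset* of
10 items (4 internal, 2 external, 2 reflective, 2 reactive) sampled
each morning from a 30-item bank, filtered by a per-item cap on
answered presentations per day and a 60-minute re-ask gap after each
answered presentation.

**Sensor triggering.** Wrist acceleration (50 Hz, synthetic) is
summarized as the per-10-s-epoch area under the curve (AUC) of the
high-passed signal. ≥10 min above threshold ⇒ physical-activity bout;
≥60 min below ⇒ sedentary bout. A triggered question refers back
Δ = (now − bout end) + 0.25 × bout length minutes and preempts the
queued question 50% of the time.

**Respondent behaviour and metrics.** A stochastic respondent drives
the watch interface state machine (20-s display, 3-s single-use undo)
producing the prompt-status taxonomy, from which the four rates are
computed: compliance (answered/scheduled), completion
(answered/delivered), undo (undos/answered) and validation
(correct/answered validation items).

## Worked example

```sh
$ uemasim simulate --days 14 --seed 42 --out events.csv
wrote 623 prompt events to events.csv
compliance 74.2%  completion 74.2%

$ uemasim metrics events.csv
scheduled  623
delivered  623
answered   462
compliance 74.2
completion 74.2
undo       4.3
validation 60.0
```

A 14-day study contains one 4-day burst, leaving 10 watch-EMA days at
~62 scheduled prompts each (623 total). With the default respondent
(75% answer probability) 462 prompts were answered; nothing was
DND-suppressed, so compliance and completion coincide at 74.2%. The
undo rate (4.3% of answered prompts) tracks the profile's undo
parameters; the validation rate is noisy here because a 10-day log
contains only 10 validation prompts.

Comparing question-selection strategies at a 50-user scale:

```sh
$ uemasim reproduce-paper --mode both --users 50 --seed 1 --out rep
random: 13050 watch-EMA days, coverage 75.1%, median daily repeats 2
filtered: 13050 watch-EMA days, coverage 33.3%, median daily repeats 4
```

Under uniform random selection a given core question appears on ~75%
of days but is answered only twice (median) per day — too thin to
estimate within-day change. The filter-based algorithm concentrates
presentations: a question appears on ~33% of days (the days its
category subset includes it) but is answered 4 times (median) on those
days.

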