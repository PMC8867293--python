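"""End-to-end study simulation producing canonical event logs.

Ties the pieces together at clock-time resolution: the burst/watch-day
calendar, per-day randomized prompt schedules, slot-class allocation,
filter-based core-question selection, optional accelerometer-triggered
questions, and the stochastic respondent.  One row per scheduled prompt
is emitted in the event-log schema consumed by :mod:`uemasim.metrics`.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from . import banks, scheduler, selection, sensors
from .config import RunConfig
from .metrics import EVENT_COLUMNS
from .respondent import respond
from .selection import QuestionSpec


def _daily_sensor_bouts(window: scheduler.SleepWakeWindow,
                        rng: np.random.Generator,
                        pa_thr: float, sb_thr: float):
    """Synthesize one waking day of accelerometry and detect its bouts.

    Times are converted from trace-relative seconds to minutes from
    midnight so they can be compared with prompt times.
    """
    hours = window.window_hours
    script: list[sensors.ActivityInterval] = []
    remaining = hours * 3600.0
    while remaining > 0:
        r = rng.random()
        if r < 0.25:
            label, dur = "active", rng.uniform(6, 25) * 60
        elif r < 0.45:
            label, dur = "sedentary", rng.uniform(45, 90) * 60
        else:
            label, dur = "transition", rng.uniform(10, 30) * 60
        dur = min(dur, remaining)
        script.append(sensors.ActivityInterval(
            label, dur, sensors.DEFAULT_INTENSITIES[label]))
        remaining -= dur
    trace = sensors.synth_accel(script, rng)
    auc = sensors.auc_epochs(trace)
    bouts = sensors.detect_bouts(auc, now_s=trace.duration_s,
                                 pa_threshold=pa_thr, sb_threshold=sb_thr)
    offset = window.prompt_start_min
    return [(b.kind, offset + b.start_s / 60.0, offset + b.end_s / 60.0)
            for b in bouts]


def simulate_study(cfg: RunConfig,
                   core_bank: list[QuestionSpec] | None = None,
                   ) -> pd.DataFrame:
    """Simulate one participant's study and return the event log."""
    if core_bank is None:
        from .io import read_question_bank
        core_bank = (read_question_bank(cfg.question_bank)
                     if cfg.question_bank else banks.default_core_bank())
    profile = cfg.respondent.to_profile()
    cal_cfg = cfg.scheduler.to_calendar_config(cfg.participant_id)
    calendar = scheduler.build_calendar(cal_cfg)

    root = np.random.SeedSequence(cfg.seed)
    bank_rng = np.random.default_rng(root.spawn(1)[0])
    state = selection.SelectionState(
        day_subset=[],
        engagement_cursor=selection.SequentialCursor(
            banks.default_engagement_bank(), bank_rng),
        validation_cursor=selection.SequentialCursor(
            banks.default_validation_bank(), bank_rng))

    rows: list[dict] = []
    day_seeds = root.spawn(len(calendar.day_types))
    for i, (date, day_type, window) in enumerate(
            zip(calendar.dates, calendar.day_types, calendar.windows)):
        if day_type != scheduler.DAY_TYPE_UEMA:
            continue
        rng = np.random.default_rng(day_seeds[i])
        sched = scheduler.build_day_schedule(date, window, rng,
                                             cfg.dnd_intervals)
        labels = selection.allocate_slot_types(len(sched), rng)
        state.start_new_day(core_bank, rng)

        pending_bouts: dict[str, tuple[str, float, float]] = {}
        all_bouts: list[tuple[str, float, float]] = []
        if cfg.sensor.enabled:
            all_bouts = _daily_sensor_bouts(window, rng,
                                            cfg.sensor.pa_threshold,
                                            cfg.sensor.sb_threshold)

        for k, (t_min, delivered) in enumerate(
                zip(sched.prompt_times_min, sched.delivered)):
            slot = labels[k]
            if slot == selection.SLOT_CORE:
                question = selection.select_question(state, t_min, rng)
            elif slot == selection.SLOT_ENGAGEMENT:
                question = state.engagement_cursor.next()
            else:
                question = state.validation_cursor.next()

            bout_used = None
            if cfg.sensor.enabled:
                # a bout stays eligible until prompted or superseded by a
                # newer bout of the same kind
                for kind, s, e in all_bouts:
                    if e <= t_min:
                        pending_bouts[kind] = (kind, s, e)
                eligible = [sensors.BoutEvent(
                    kind, s * 60.0, e * 60.0,
                    sensors.delta_minutes(s * 60.0, e * 60.0, t_min * 60.0))
                    for kind, s, e in pending_bouts.values()]
                question, bout_used = sensors.maybe_trigger(
                    eligible, question, rng)
                if bout_used is not None:
                    pending_bouts.pop(bout_used.kind, None)
                    slot = question.category

            ev = respond(f"{cfg.participant_id}-{date.isoformat()}-{k:02d}",
                         t_min, delivered, question, slot, profile, rng)
            if ev.answered and slot == selection.SLOT_CORE:
                selection.record_outcome(state, question, True, t_min)

            base = dt.datetime.combine(date, dt.time())
            rows.append({
                "participant_id": cfg.participant_id,
                "date": date.isoformat(),
                "prompt_id": ev.prompt_id,
                "timestamp": (base + dt.timedelta(minutes=t_min)).isoformat(),
                "scheduled_min": round(t_min, 4),
                "day_type": day_type,
                "slot_type": slot,
                "question_id": question.id,
                "category": question.category,
                "delivered": delivered,
                "status": ev.status,
                "answer": ev.answer,
                "latency_s": ev.latency_s,
                "undo_used": ev.undo_used,
                "correct": (ev.answer == question.correct_answer
                            if ev.answered and question.correct_answer
                            else None),
            })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
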