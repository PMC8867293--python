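"""Prompt scheduling for smartwatch microinteraction EMA.

The watch asks four single-tap questions per clock hour at randomized
times, with a guaranteed minimum gap of eight minutes between consecutive
prompts.  Within each hour the n-th prompt offset (minutes past the hour)
follows the recurrence

    P_n = U[0, MaxTimeAvailable_n) + gap + P_{n-1},        P_0 = 0
    MaxTimeAvailable_n = 55 - ((4 - n + 1) * gap) - P_{n-1}

so that all four prompts land in [8, 55) and the remaining draws always
fit.  Because the last offset is below 55 and the next hour's first
offset is at least 8, the cross-hour gap is structurally >= 13 minutes.

A full 24-hour candidate schedule is generated and then clipped to the
participant's waking window (15 minutes after wake to 15 minutes before
sleep).  Do-not-disturb intervals suppress *delivery*, not scheduling.

The study calendar alternates 4-day smartphone-EMA measurement bursts
(always containing Saturday and Sunday, every two weeks, at most 26 per
year) with watch-EMA days on the remaining dates.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

GAP_MIN = 8.0
PROMPTS_PER_HOUR = 4
#: Latest feasible minute-offset bound: 60 - (60 - 55) = 55 leaves room so
#: the following hour's first prompt keeps the 8-minute guarantee.
HOUR_BUDGET = 55.0
#: Prompting starts this many minutes after wake and stops this many
#: minutes before sleep.
WAKE_MARGIN_MIN = 15.0

DAY_TYPE_BURST = "ema_burst"
DAY_TYPE_UEMA = "uema"
DAY_TYPE_NONE = "none"

_WEEKDAYS = {
    "monday": 0, "tuesday": 1, "wednesday": 2, "thursday": 3,
    "friday": 4, "saturday": 5, "sunday": 6,
}


def max_time_available(n: int, p_prev: float, *, gap: float = GAP_MIN,
                       per_hour: int = PROMPTS_PER_HOUR) -> float:
    """Minutes available for the n-th draw of the hour (n is 1-based)."""
    return HOUR_BUDGET - ((per_hour - n + 1) * gap) - p_prev


def generate_hour_prompts(rng: np.random.Generator) -> list[float]:
    """Generate the four within-hour prompt offsets, in minutes.

    Offsets are strictly increasing, lie in [8, 55), and consecutive
    differences are at least eight minutes.
    """
    p_prev = 0.0
    offsets: list[float] = []
    for n in range(1, PROMPTS_PER_HOUR + 1):
        avail = max_time_available(n, p_prev)
        p_prev = rng.uniform(0.0, avail) + GAP_MIN + p_prev
        offsets.append(p_prev)
    return offsets


def simulate_hours(n_hours: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorized bulk version of :func:`generate_hour_prompts`.

    Returns an ``(n_hours, 4)`` array of offsets; used for large-scale
    property checks of the scheduling recurrence.
    """
    p_prev = np.zeros(n_hours)
    cols = []
    for n in range(1, PROMPTS_PER_HOUR + 1):
        avail = HOUR_BUDGET - ((PROMPTS_PER_HOUR - n + 1) * GAP_MIN) - p_prev
        p_prev = rng.uniform(0.0, 1.0, n_hours) * avail + GAP_MIN + p_prev
        cols.append(p_prev)
    return np.column_stack(cols)


def prompting_opportunities(window_hours: float,
                            per_hour: int = PROMPTS_PER_HOUR) -> int:
    """Nominal scheduled-prompt count for a waking window of given length.

    This is the accounting used in study-design arithmetic (a 15.5-hour
    window at 4 prompts/hour gives 62 opportunities); realized daily
    totals from :func:`build_day_schedule` fluctuate around it because
    the 24-hour schedule is clipped at the window edges.
    """
    return int(math.floor(window_hours * per_hour))


def _parse_clock(value: dt.time | str) -> dt.time:
    if isinstance(value, dt.time):
        return value
    return dt.time.fromisoformat(value)


@dataclass(frozen=True)
class SleepWakeWindow:
    """A day's self-reported waking window.

    When a day's sleep/wake report is missing the calendar reuses the
    previous day's values, mirroring the watch's fallback behaviour.
    """

    sleep_time: dt.time
    wake_time: dt.time

    @property
    def prompt_start_min(self) -> float:
        """Minutes from midnight when prompting may start."""
        return _minutes(self.wake_time) + WAKE_MARGIN_MIN

    @property
    def prompt_end_min(self) -> float:
        """Minutes from midnight when prompting must stop."""
        return _minutes(self.sleep_time) - WAKE_MARGIN_MIN

    @property
    def window_hours(self) -> float:
        return max(self.prompt_end_min - self.prompt_start_min, 0.0) / 60.0


def _minutes(t: dt.time) -> float:
    return t.hour * 60.0 + t.minute + t.second / 60.0


@dataclass
class DaySchedule:
    """Scheduled prompts for one day, as minutes from midnight.

    ``delivered`` flags prompts not suppressed by a do-not-disturb
    interval; suppressed prompts stay in the schedule (they count as
    scheduled-but-not-delivered in compliance accounting).
    """

    date: dt.date
    prompt_times_min: list[float]
    delivered: list[bool]
    dnd_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.prompt_times_min)

    def prompt_datetimes(self) -> list[dt.datetime]:
        base = dt.datetime.combine(self.date, dt.time())
        return [base + dt.timedelta(minutes=m) for m in self.prompt_times_min]


def build_day_schedule(date: dt.date, window: SleepWakeWindow,
                       rng: np.random.Generator,
                       dnd_intervals: list[tuple[float, float]] | None = None,
                       ) -> DaySchedule:
    """Generate a full 24-hour schedule and clip it to the waking window.

    Times are stored at one-second resolution.  A degenerate window
    (start at or after end) yields an empty schedule with a warning.
    """
    dnd_intervals = list(dnd_intervals or [])
    start, end = window.prompt_start_min, window.prompt_end_min
    if start >= end:
        logger.warning("degenerate waking window on %s: start %.1f >= end %.1f",
                       date, start, end)
        return DaySchedule(date, [], [], dnd_intervals)

    times: list[float] = []
    for hour in range(24):
        for off in generate_hour_prompts(rng):
            t = hour * 60.0 + off
            # 1-second resolution
            t = round(t * 60.0) / 60.0
            if start <= t <= end:
                times.append(t)
    delivered = [not any(a <= t < b for a, b in dnd_intervals) for t in times]
    return DaySchedule(date, times, delivered, dnd_intervals)


@dataclass(frozen=True)
class CalendarConfig:
    participant_id: str = "p001"
    start_date: dt.date = dt.date(2021, 1, 4)
    study_days: int = 365
    #: Weekday of the first burst day; a 4-day block starting Thu, Fri or
    #: Sat is the only way to contain both Saturday and Sunday.
    burst_anchor: str = "friday"
    burst_length_days: int = 4
    burst_period_days: int = 14
    max_bursts: int = 26
    #: Days at the start before the watch arrives (no prompting at all).
    pre_study_days: int = 0
    sleep_time: dt.time = dt.time(23, 0)
    wake_time: dt.time = dt.time(7, 0)

    def __post_init__(self):
        anchor = self.burst_anchor.lower()
        if anchor not in _WEEKDAYS:
            raise ValueError(f"unknown weekday {self.burst_anchor!r}")
        block = {(_WEEKDAYS[anchor] + i) % 7 for i in range(self.burst_length_days)}
        if not {5, 6} <= block:
            raise ValueError(
                f"burst anchored on {self.burst_anchor} does not contain "
                "both Saturday and Sunday")
        gap = self.burst_period_days - self.burst_length_days
        if gap < 7:
            raise ValueError(
                f"burst period {self.burst_period_days} d leaves a "
                f"{gap}-day gap between bursts; at least 7 required")


@dataclass
class StudyCalendar:
    """Per-day study-phase assignment for one participant."""

    participant_id: str
    start_date: dt.date
    day_types: list[str]
    windows: list[SleepWakeWindow]

    @property
    def dates(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=i)
                for i in range(len(self.day_types))]

    def count(self, day_type: str) -> int:
        return sum(1 for d in self.day_types if d == day_type)

    @property
    def n_bursts(self) -> int:
        runs = 0
        prev = None
        for d in self.day_types:
            if d == DAY_TYPE_BURST and prev != DAY_TYPE_BURST:
                runs += 1
            prev = d
        return runs


def build_calendar(config: CalendarConfig,
                   window_overrides: dict[dt.date, SleepWakeWindow] | None = None,
                   ) -> StudyCalendar:
    """Lay out burst and watch-EMA days over the study period.

    Bursts are 4 consecutive days containing Saturday and Sunday, repeat
    every two weeks (>= 7 clear days between bursts), and are capped at
    26 per study.  Every remaining day after the pre-study lead-in is a
    watch-EMA day.
    """
    window_overrides = window_overrides or {}
    anchor_wd = _WEEKDAYS[config.burst_anchor.lower()]
    first_anchor = (anchor_wd - config.start_date.weekday()) % 7

    day_types = [DAY_TYPE_NONE] * min(config.pre_study_days, config.study_days) \
        + [DAY_TYPE_UEMA] * max(config.study_days - config.pre_study_days, 0)

    n_bursts = 0
    start = first_anchor
    while start < config.study_days and n_bursts < config.max_bursts:
        stop = min(start + config.burst_length_days, config.study_days)
        for i in range(start, stop):
            day_types[i] = DAY_TYPE_BURST
        n_bursts += 1
        start += config.burst_period_days

    default = SleepWakeWindow(config.sleep_time, config.wake_time)
    windows: list[SleepWakeWindow] = []
    current = default
    for i in range(config.study_days):
        date = config.start_date + dt.timedelta(days=i)
        if date in window_overrides:
            current = window_overrides[date]  # reused until next report
        windows.append(current)
    return StudyCalendar(config.participant_id, config.start_date,
                         day_types, windows)
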