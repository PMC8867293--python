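"""Response-behaviour rates and per-question presentation statistics.

Four rates characterize answering behaviour::

    compliance (%) = answered / scheduled x 100   (scheduled includes
                                                   DND-suppressed prompts)
    completion (%) = answered / delivered x 100
    undo       (%) = undo count / answered x 100
    validation (%) = validation answered correctly / validation answered x 100

Rates with a zero denominator are *undefined* (None), never zero.
Day- and participant-level summaries are unweighted means of per-unit
rates by default; prompt-count weighting is available, under which the
aggregate equals the pooled rate exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .selection import CORE_CATEGORIES, QuestionSpec
from .respondent import STATUS_ANSWERED

#: Canonical event-log columns written by the simulators.
EVENT_COLUMNS = [
    "participant_id", "date", "prompt_id", "timestamp", "scheduled_min",
    "day_type", "slot_type", "question_id", "category", "delivered",
    "status", "answer", "latency_s", "undo_used", "correct",
]


@dataclass
class ResponseSummary:
    n_scheduled: int
    n_delivered: int
    n_answered: int
    n_undo: int
    n_validation_answered: int
    n_validation_correct: int
    compliance_pct: float | None
    completion_pct: float | None
    undo_pct: float | None
    validation_pct: float | None
    aggregation_level: str = "pooled"
    undefined_rates: tuple[str, ...] = ()


def _rate(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def _counts(df: pd.DataFrame) -> dict[str, int]:
    answered = df["status"] == STATUS_ANSWERED
    val = answered & (df["slot_type"] == "validation")
    return {
        "n_scheduled": len(df),
        "n_delivered": int(df["delivered"].sum()),
        "n_answered": int(answered.sum()),
        "n_undo": int((df.loc[answered, "undo_used"] == True).sum()),  # noqa: E712
        "n_validation_answered": int(val.sum()),
        "n_validation_correct": int(
            (df.loc[val, "correct"] == True).sum()),  # noqa: E712
    }


def _summary_from_counts(c: dict[str, int], level: str,
                         rates: dict[str, float | None] | None = None,
                         ) -> ResponseSummary:
    if rates is None:
        rates = {
            "compliance_pct": _rate(c["n_answered"], c["n_scheduled"]),
            "completion_pct": _rate(c["n_answered"], c["n_delivered"]),
            "undo_pct": _rate(c["n_undo"], c["n_answered"]),
            "validation_pct": _rate(c["n_validation_correct"],
                                    c["n_validation_answered"]),
        }
    undefined = tuple(k for k, v in rates.items() if v is None)
    return ResponseSummary(**c, **rates, aggregation_level=level,
                           undefined_rates=undefined)


def compute_rates(events: pd.DataFrame, level: str = "pooled",
                  weighted: bool = False) -> ResponseSummary:
    """Compute the four response-behaviour rates from an event log.

    ``level`` is ``"pooled"`` (ratio of totals), ``"day"`` or
    ``"participant"`` (means of per-unit rates, unweighted unless
    ``weighted``, in which case units are weighted by their denominators
    and the result coincides with the pooled rate).
    """
    totals = _counts(events)
    if level == "pooled" or weighted:
        return _summary_from_counts(totals, level)
    if level == "day":
        keys = ["participant_id", "date"]
    elif level == "participant":
        keys = ["participant_id"]
    else:
        raise ValueError(f"unknown aggregation level {level!r}")

    per_unit: dict[str, list[float]] = {k: [] for k in (
        "compliance_pct", "completion_pct", "undo_pct", "validation_pct")}
    for _, grp in events.groupby(keys):
        c = _counts(grp)
        for name, num, den in (
                ("compliance_pct", c["n_answered"], c["n_scheduled"]),
                ("completion_pct", c["n_answered"], c["n_delivered"]),
                ("undo_pct", c["n_undo"], c["n_answered"]),
                ("validation_pct", c["n_validation_correct"],
                 c["n_validation_answered"])):
            r = _rate(num, den)
            if r is not None:
                per_unit[name].append(r)
    rates = {k: (float(np.mean(v)) if v else None)
             for k, v in per_unit.items()}
    return _summary_from_counts(totals, level, rates)


@dataclass
class PresentationStats:
    """Per-core-question day coverage and within-day repetition."""

    per_question: pd.DataFrame   # question_id, category, days_presented,
    #                              coverage, median_daily_answered
    n_days: int

    @property
    def mean_coverage(self) -> float:
        return float(self.per_question["coverage"].mean())

    @property
    def median_repeats(self) -> float:
        """Median across questions of the per-question median daily
        answered count on presented days."""
        return float(self.per_question["median_daily_answered"].median())


def presentation_stats(events: pd.DataFrame,
                       bank: list[QuestionSpec]) -> PresentationStats:
    """Day-coverage fraction and median answered repetitions per core item.

    Coverage counts days with at least one *answered* presentation over
    all participant-days in the log; the median counts answered
    presentations on those presented days only.
    """
    core_ids = {q.id: q.category for q in bank
                if q.category in CORE_CATEGORIES}
    logged = set(events.loc[events["category"].isin(CORE_CATEGORIES),
                            "question_id"].unique())
    unknown = logged - set(core_ids)
    if unknown:
        raise ValueError(f"questions not in bank: {sorted(unknown)}")

    day_index = events[["participant_id", "date"]].drop_duplicates()
    n_days = len(day_index)
    answered = events[(events["status"] == STATUS_ANSWERED)
                      & events["question_id"].isin(core_ids)]
    daily = (answered.groupby(["question_id", "participant_id", "date"])
             .size().rename("count").reset_index())

    rows = []
    for qid, cat in core_ids.items():
        counts = daily.loc[daily["question_id"] == qid, "count"]
        rows.append({
            "question_id": qid,
            "category": cat,
            "days_presented": len(counts),
            "coverage": len(counts) / n_days if n_days else np.nan,
            "median_daily_answered": (float(counts.median())
                                      if len(counts) else np.nan),
        })
    return PresentationStats(pd.DataFrame(rows), n_days)
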