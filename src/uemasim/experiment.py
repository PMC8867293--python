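"""Slot-level question-sampling simulation: random vs filter-based.

Reproduces the study-design experiment that motivated filter-based
selection: 300 simulated users, 365-day studies with 261 watch-EMA days
each (78,300 simulated days), 62 prompting opportunities per day of
which 55 are core-construct slots, and a 75% chance that any scheduled
prompt is answered.

Two selection modes are compared:

* ``random`` — every core slot draws uniformly from the 30-item bank
  with no filters (the pilot behaviour);
* ``filtered`` — the full day-subset / per-day-cap / 60-minute-re-ask
  pipeline from :mod:`uemasim.selection`.

The simulation abstracts clock time to a slot sequence: 62 slots evenly
spaced over the 15.5-hour prompting span (15 minutes apart), which
preserves the 60-minute filter's effect of roughly four slots per hour.
Under random selection a question is answered on ~75% of days but
typically only twice per day; filtering concentrates presentations so
that on the ~33% of days a question is in the day subset it is answered
about 4 times — enough to estimate within-day slopes.

The analytic check for random mode: with A answered core slots per day,
a given item is missed all day with probability (29/30)^A, so coverage
is 1 − (29/30)^41 ≈ 75% at A = 41 ≈ 0.75 × 55.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import selection
from .banks import default_core_bank
from .metrics import ResponseSummary
from .selection import QuestionSpec

MODE_RANDOM = "random"
MODE_FILTERED = "filtered"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the sampling simulation."""

    n_users: int = 300
    study_days: int = 365
    uema_days: int = 261
    sleep_h: float = 8.0
    wake_h: float = 16.0
    prompting_h: float = 15.5
    prompts_per_day: int = 62
    core_slots: int = 55
    answer_prob: float = 0.75
    mode: str = MODE_FILTERED
    seed: int = 0

    def __post_init__(self):
        if self.uema_days > self.study_days:
            raise ValueError("uema_days cannot exceed study_days")
        if self.core_slots > self.prompts_per_day:
            raise ValueError("core_slots cannot exceed prompts_per_day")
        if self.mode not in (MODE_RANDOM, MODE_FILTERED):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def total_uema_days(self) -> int:
        return self.n_users * self.uema_days

    @property
    def slot_spacing_min(self) -> float:
        return self.prompting_h * 60.0 / self.prompts_per_day


@dataclass
class SamplingResult:
    mode: str
    config: SimConfig
    per_question: pd.DataFrame
    n_days: int
    summary: ResponseSummary
    #: per-question daily answered counts histogram, for inspection
    count_hist: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def mean_coverage_pct(self) -> float:
        return 100.0 * float(self.per_question["coverage"].mean())

    @property
    def median_repeats(self) -> float:
        return float(self.per_question["median_daily_answered"].median())


def random_mode_coverage_closed_form(n_answered: int = 41,
                                     bank_size: int = 30) -> float:
    """P(a given item is answered >= once in a day) under uniform
    selection with ``n_answered`` answered core slots."""
    return 1.0 - ((bank_size - 1) / bank_size) ** n_answered


def _simulate_random(cfg: SimConfig, bank: list[QuestionSpec],
                     rng: np.random.Generator) -> np.ndarray:
    """All users at once; returns (total_days, n_questions) answered
    counts."""
    n_days = cfg.total_uema_days
    nq = len(bank)
    counts = np.zeros((n_days, nq), dtype=np.int32)
    items = rng.integers(0, nq, size=(n_days, cfg.core_slots))
    answered = rng.random(size=(n_days, cfg.core_slots)) < cfg.answer_prob
    day_idx = np.repeat(np.arange(n_days), cfg.core_slots)
    np.add.at(counts, (day_idx[answered.ravel()],
                       items.ravel()[answered.ravel()]), 1)
    return counts


def _simulate_filtered_user(cfg: SimConfig, bank: list[QuestionSpec],
                            rng: np.random.Generator,
                            counts_out: np.ndarray, day0: int) -> None:
    """One user's watch-EMA days through the real selection pipeline."""
    nq = len(bank)
    caps = np.array([q.max_per_day for q in bank])
    by_cat: dict[str, np.ndarray] = {}
    for cat in selection.SUBSET_COMPOSITION:
        by_cat[cat] = np.array([i for i, q in enumerate(bank)
                                if q.category == cat])
    spacing = cfg.slot_spacing_min
    gap = selection.REASK_GAP_MIN
    n_slots = cfg.prompts_per_day

    for d in range(cfg.uema_days):
        # day-level subset: 4 internal + 2 external + 2 reflective + 2 reactive
        subset = np.concatenate([
            pool[rng.choice(len(pool), size=k, replace=False)]
            for cat, k in selection.SUBSET_COMPOSITION.items()
            for pool in (by_cat[cat],)])
        sub_caps = caps[subset]
        n_ans = np.zeros(len(subset), dtype=np.int64)
        last = np.full(len(subset), -np.inf)

        core_pos = np.sort(rng.choice(n_slots, size=cfg.core_slots,
                                      replace=False))
        u_pick = rng.random(cfg.core_slots)
        u_ans = rng.random(cfg.core_slots) < cfg.answer_prob
        row = counts_out[day0 + d]
        for j, pos in enumerate(core_pos):
            t = pos * spacing
            elig = np.flatnonzero((n_ans < sub_caps) & (t - last >= gap))
            if elig.size == 0:
                continue  # fallback engagement item; no core answered
            k = elig[int(u_pick[j] * elig.size)]
            if u_ans[j]:
                n_ans[k] += 1
                last[k] = t
        np.add.at(row, subset, n_ans)


def run_sampling_simulation(config: SimConfig,
                            bank: list[QuestionSpec] | None = None,
                            ) -> SamplingResult:
    """Run the sampling simulation in the configured mode."""
    bank = bank if bank is not None else default_core_bank()
    root = np.random.SeedSequence(config.seed)
    if config.mode == MODE_RANDOM:
        rng = np.random.default_rng(root)
        counts = _simulate_random(config, bank, rng)
    else:
        counts = np.zeros((config.total_uema_days, len(bank)),
                          dtype=np.int32)
        for u, ss in enumerate(root.spawn(config.n_users)):
            _simulate_filtered_user(config, bank, np.random.default_rng(ss),
                                    counts, u * config.uema_days)

    n_days = counts.shape[0]
    rows = []
    hist: dict[str, np.ndarray] = {}
    for j, q in enumerate(bank):
        col = counts[:, j]
        presented = col > 0
        n_pres = int(presented.sum())
        rows.append({
            "question_id": q.id,
            "category": q.category,
            "max_per_day": q.max_per_day,
            "days_presented": n_pres,
            "coverage": n_pres / n_days,
            "median_daily_answered": (float(np.median(col[presented]))
                                      if n_pres else np.nan),
            "mean_daily_answered": (float(col[presented].mean())
                                    if n_pres else np.nan),
            "max_daily_answered": int(col.max()),
        })
        hist[q.id] = np.bincount(col)

    n_scheduled = n_days * config.prompts_per_day
    n_answered_core = int(counts.sum())
    # non-core slots answered at the same per-prompt probability
    rng2 = np.random.default_rng(root.spawn(1)[0])
    n_other = n_days * (config.prompts_per_day - config.core_slots)
    n_answered_other = int(rng2.binomial(n_other, config.answer_prob))
    n_answered = n_answered_core + n_answered_other
    summary = ResponseSummary(
        n_scheduled=n_scheduled, n_delivered=n_scheduled,
        n_answered=n_answered, n_undo=0, n_validation_answered=0,
        n_validation_correct=0,
        compliance_pct=100.0 * n_answered / n_scheduled,
        completion_pct=100.0 * n_answered / n_scheduled,
        undo_pct=None, validation_pct=None,
        aggregation_level="pooled",
        undefined_rates=("undo_pct", "validation_pct"))
    return SamplingResult(config.mode, config, pd.DataFrame(rows),
                          n_days, summary, hist)


def comparison_table(random_result: SamplingResult,
                     filtered_result: SamplingResult) -> pd.DataFrame:
    """Side-by-side per-question comparison of the two selection modes."""
    r = random_result.per_question.set_index("question_id")
    f = filtered_result.per_question.set_index("question_id")
    out = pd.DataFrame({
        "category": r["category"],
        "coverage_random": r["coverage"],
        "coverage_filtered": f["coverage"],
        "median_daily_random": r["median_daily_answered"],
        "median_daily_filtered": f["median_daily_answered"],
        "max_daily_random": r["max_daily_answered"],
        "max_daily_filtered": f["max_daily_answered"],
    })
    return out.reset_index()
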