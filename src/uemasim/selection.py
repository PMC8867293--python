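"""Filter-based question selection for watch-EMA prompts.

Each prompt presents exactly one question.  Daily slots are split among
three question classes — core-construct (nominally 90%), engagement
(8%) and validation (2%) — and core slots draw from a *day-level
subset* of 10 items (4 internal, 2 external, 2 reflective, 2 reactive)
sampled each morning from the 30-item core bank.  Two filters shape
within-day repetition of core items:

* a per-question cap on *answered* presentations per day, and
* a 60-minute re-ask gap after an answered presentation (an unanswered
  item may repeat at the very next prompt).

Engagement and validation items are consumed sequentially from a
shuffled-once ordering so they do not repeat until their bank is
exhausted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

CORE_CATEGORIES = ("internal", "external", "reflective", "reactive")
ALL_CATEGORIES = CORE_CATEGORIES + ("engagement", "validation",
                                    "sensor_pa", "sensor_sb")

#: Day-level subset composition drawn from the core bank each morning.
SUBSET_COMPOSITION = {"internal": 4, "external": 2, "reflective": 2,
                      "reactive": 2}

SLOT_CORE = "core"
SLOT_ENGAGEMENT = "engagement"
SLOT_VALIDATION = "validation"

#: Minutes an answered item is ineligible for re-presentation.
REASK_GAP_MIN = 60.0


@dataclass(frozen=True)
class QuestionSpec:
    """One single-tap watch question."""

    id: str
    text: str
    category: str
    answer_options: tuple[str, ...]
    max_per_day: int = 8
    correct_answer: str | None = None

    def __post_init__(self):
        if self.category not in ALL_CATEGORIES:
            raise ValueError(f"{self.id}: unknown category {self.category!r}")
        if not 2 <= len(self.answer_options) <= 3:
            raise ValueError(
                f"{self.id}: needs 2-3 answer options, got "
                f"{len(self.answer_options)}")
        if self.max_per_day < 1:
            raise ValueError(f"{self.id}: max_per_day must be positive")
        if self.category == "validation":
            if self.correct_answer is None:
                raise ValueError(f"{self.id}: validation item needs a "
                                 "correct_answer")
            if self.correct_answer not in self.answer_options:
                raise ValueError(
                    f"{self.id}: correct_answer {self.correct_answer!r} not "
                    "among answer options")


def split_by_category(bank: list[QuestionSpec]) -> dict[str, list[QuestionSpec]]:
    out: dict[str, list[QuestionSpec]] = {c: [] for c in ALL_CATEGORIES}
    for q in bank:
        out[q.category].append(q)
    return out


def draw_day_subset(core_bank: list[QuestionSpec],
                    rng: np.random.Generator) -> list[QuestionSpec]:
    """Sample the day-level subset: 4 internal + 2 external + 2 reflective
    + 2 reactive, uniformly without replacement within each category."""
    by_cat = split_by_category(core_bank)
    subset: list[QuestionSpec] = []
    for cat, k in SUBSET_COMPOSITION.items():
        pool = by_cat[cat]
        if len(pool) < k:
            raise ValueError(
                f"core bank has only {len(pool)} {cat!r} items; {k} needed")
        idx = rng.choice(len(pool), size=k, replace=False)
        subset.extend(pool[i] for i in idx)
    return subset


def slot_quotas(n_prompts: int) -> dict[str, int]:
    """Nominal daily class quotas for ``n_prompts`` scheduled slots.

    Validation gets round(2%) (at least 1 when any prompt is scheduled),
    engagement round(8%) (at least 1 once two or more prompts exist),
    core the nominal 90%; any unallocated remainder is folded into core
    by :func:`allocate_slot_types`.  At the canonical 62 prompts/day this
    yields 55 core / 5 engagement / 1 validation (+1 spare).
    """
    if n_prompts <= 0:
        return {SLOT_CORE: 0, SLOT_ENGAGEMENT: 0, SLOT_VALIDATION: 0,
                "spare": 0}
    validation = max(1, round(0.02 * n_prompts))
    engagement = max(1, round(0.08 * n_prompts)) if n_prompts >= 2 else 0
    engagement = min(engagement, n_prompts - validation)
    core = max(int(math.floor(0.90 * n_prompts)), 0)
    core = min(core, n_prompts - validation - engagement)
    spare = n_prompts - core - engagement - validation
    return {SLOT_CORE: core, SLOT_ENGAGEMENT: engagement,
            SLOT_VALIDATION: validation, "spare": spare}


def allocate_slot_types(n_prompts: int, rng: np.random.Generator) -> list[str]:
    """Assign a slot class to each of the day's prompts, randomly
    interleaved.  The quota remainder goes to core (the nominal 90%
    class)."""
    q = slot_quotas(n_prompts)
    labels = ([SLOT_CORE] * (q[SLOT_CORE] + q["spare"])
              + [SLOT_ENGAGEMENT] * q[SLOT_ENGAGEMENT]
              + [SLOT_VALIDATION] * q[SLOT_VALIDATION])
    perm = rng.permutation(len(labels))
    return [labels[i] for i in perm]


class SequentialCursor:
    """Shuffled-once sequential iterator over a question bank.

    Items never repeat until the whole bank is exhausted, after which
    the bank is reshuffled; this gives engagement/validation items their
    multi-month no-repeat horizon.
    """

    def __init__(self, bank: list[QuestionSpec], rng: np.random.Generator):
        if not bank:
            raise ValueError("empty bank")
        self._bank = list(bank)
        self._rng = rng
        self._order = list(rng.permutation(len(bank)))
        self._pos = 0

    def next(self) -> QuestionSpec:
        if self._pos >= len(self._order):
            self._order = list(self._rng.permutation(len(self._bank)))
            self._pos = 0
        q = self._bank[self._order[self._pos]]
        self._pos += 1
        return q


@dataclass
class SelectionState:
    """Mutable per-day selection state for one participant.

    ``now`` arguments throughout are minutes from midnight of the
    current day; ``last_answered_min`` may go negative to carry the
    60-minute filter across midnight (not needed in practice because
    prompting pauses overnight, but harmless).
    """

    day_subset: list[QuestionSpec]
    engagement_cursor: SequentialCursor
    validation_cursor: SequentialCursor
    answered_count: dict[str, int] = field(default_factory=dict)
    last_answered_min: dict[str, float] = field(default_factory=dict)

    def start_new_day(self, core_bank: list[QuestionSpec],
                      rng: np.random.Generator) -> None:
        self.day_subset = draw_day_subset(core_bank, rng)
        self.answered_count.clear()
        self.last_answered_min.clear()


def eligible_core(state: SelectionState, now_min: float,
                  reask_gap_min: float = REASK_GAP_MIN,
                  ) -> list[QuestionSpec]:
    """Day-subset items not capped out and not answered in the last hour."""
    out = []
    for q in state.day_subset:
        if state.answered_count.get(q.id, 0) >= q.max_per_day:
            continue
        last = state.last_answered_min.get(q.id)
        if last is not None and now_min - last < reask_gap_min:
            continue
        out.append(q)
    return out


def select_question(state: SelectionState, now_min: float,
                    rng: np.random.Generator,
                    reask_gap_min: float = REASK_GAP_MIN) -> QuestionSpec:
    """Pick the core question for a prompt at ``now_min``.

    Falls back to the next engagement item when every subset item is
    capped or inside its re-ask gap, so the prompt budget is preserved
    without violating either filter.
    """
    candidates = eligible_core(state, now_min, reask_gap_min)
    if not candidates:
        logger.info("no eligible core item at t=%.1f min; presenting an "
                    "engagement item instead", now_min)
        return state.engagement_cursor.next()
    return candidates[int(rng.integers(len(candidates)))]


def record_outcome(state: SelectionState, question: QuestionSpec,
                   answered: bool, time_min: float) -> SelectionState:
    """Update selection state after a prompt resolves.

    Only *answered* prompts advance the cap counter and the re-ask
    clock; a missed or dismissed item stays fully eligible.
    """
    if answered:
        state.answered_count[question.id] = \
            state.answered_count.get(question.id, 0) + 1
        state.last_answered_min[question.id] = time_min
    return state
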