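"""Simulated participant interaction with delivered prompts.

The watch interface gives each question 20 seconds on screen.  Answering
shows a thank-you screen with a 3-second, single-use Undo button.  The
resulting prompt-status taxonomy:

========================  =================================================
answered                  an answer was recorded (possibly after an undo)
missed                    no interaction for 20 s
never_started             swiped away on the question screen
completed_then_dismissed  answered, then swiped away on the undo screen
partially_completed       answered, pressed undo, never re-answered
not_delivered             suppressed by do-not-disturb
========================  =================================================

:func:`prompt_lifecycle` is the deterministic state machine mapping an
action sequence to a status; :func:`respond` wraps it stochastically
with a :class:`RespondentProfile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .selection import QuestionSpec

DISPLAY_WINDOW_S = 20.0
UNDO_WINDOW_S = 3.0

STATUS_ANSWERED = "answered"
STATUS_MISSED = "missed"
STATUS_NEVER_STARTED = "never_started"
STATUS_COMPLETED_DISMISSED = "completed_then_dismissed"
STATUS_PARTIAL = "partially_completed"
STATUS_NOT_DELIVERED = "not_delivered"


@dataclass(frozen=True)
class RespondentProfile:
    """Stochastic interaction model for one simulated participant.

    ``answer_prob`` applies per delivered prompt.  Conditional on an
    initial answer, ``undo_prob`` is the chance the undo button is
    pressed, after which ``undo_abandon_prob`` is the chance no second
    answer arrives (partially completed); without an undo,
    ``dismiss_prob`` is the chance the undo screen is swiped away
    (completed then dismissed).  For unanswered prompts ``dismiss_prob``
    is the chance of a swipe on the question screen (never started)
    rather than a timeout (missed).

    Default latency parameters give mean ~4.8 s, SD ~1.4 s, truncated
    to the 20-second display window.
    """

    answer_prob: float = 0.75
    dismiss_prob: float = 0.02
    undo_prob: float = 0.05
    undo_abandon_prob: float = 0.10
    validation_error_rate: float = 0.07
    latency_mu: float = 1.5278      # log-seconds
    latency_sigma: float = 0.2856

    def __post_init__(self):
        for name in ("answer_prob", "dismiss_prob", "undo_prob",
                     "undo_abandon_prob", "validation_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class PromptEvent:
    """Outcome of one scheduled prompt."""

    prompt_id: str
    scheduled_min: float                 # minutes from midnight
    delivered: bool
    question_id: str
    slot_type: str
    category: str
    status: str
    answer: str | None = None
    latency_s: float | None = None
    undo_used: bool = False
    extra: dict = field(default_factory=dict)

    @property
    def answered(self) -> bool:
        return self.status == STATUS_ANSWERED


# -- deterministic interface state machine ---------------------------------

def prompt_lifecycle(actions: Sequence[tuple]) -> str:
    """Map an interaction sequence to a prompt status.

    Actions are tuples: ``("answer", t_s, value)``, ``("swipe", t_s)``,
    ``("undo",)``, ``("timeout",)``.  Times are seconds since prompt
    display; answers after the 20-s window or a second undo raise.
    """
    answered_once = False
    undo_used = False
    on_undo_screen = False
    for act in actions:
        kind = act[0]
        if kind == "answer":
            t = act[1]
            if not 0.0 < t <= DISPLAY_WINDOW_S:
                raise ValueError(f"answer at t={t} outside display window")
            answered_once = True
            on_undo_screen = True
        elif kind == "swipe":
            return (STATUS_COMPLETED_DISMISSED if on_undo_screen
                    else STATUS_NEVER_STARTED)
        elif kind == "undo":
            if not on_undo_screen:
                raise ValueError("undo before any answer")
            if undo_used:
                raise ValueError("only one undo is permitted")
            undo_used = True
            on_undo_screen = False
            answered_once = False  # must re-answer to count
        elif kind == "timeout":
            return STATUS_ANSWERED if answered_once else (
                STATUS_PARTIAL if undo_used else STATUS_MISSED)
        else:
            raise ValueError(f"unknown action {kind!r}")
    # sequence ended without timeout/swipe: the undo window lapsing
    # finalizes an answer
    if answered_once:
        return STATUS_ANSWERED
    return STATUS_PARTIAL if undo_used else STATUS_MISSED


# -- stochastic wrapper ----------------------------------------------------

def _sample_latency(profile: RespondentProfile,
                    rng: np.random.Generator) -> float:
    for _ in range(100):
        x = float(rng.lognormal(profile.latency_mu, profile.latency_sigma))
        if 0.0 < x <= DISPLAY_WINDOW_S:
            return x
    return DISPLAY_WINDOW_S  # pathological parameters


def _sample_answer(question: QuestionSpec, profile: RespondentProfile,
                   rng: np.random.Generator) -> str:
    opts = question.answer_options
    if question.category == "validation" and question.correct_answer:
        if rng.random() >= profile.validation_error_rate:
            return question.correct_answer
        wrong = [o for o in opts if o != question.correct_answer]
        return wrong[int(rng.integers(len(wrong)))]
    return opts[int(rng.integers(len(opts)))]


def respond(prompt_id: str, scheduled_min: float, delivered: bool,
            question: QuestionSpec, slot_type: str,
            profile: RespondentProfile,
            rng: np.random.Generator) -> PromptEvent:
    """Simulate one prompt end-to-end and return its event record."""
    ev = PromptEvent(prompt_id, scheduled_min, delivered, question.id,
                     slot_type, question.category,
                     status=STATUS_NOT_DELIVERED)
    if not delivered:
        return ev
    if rng.random() < profile.answer_prob:
        latency = _sample_latency(profile, rng)
        answer = _sample_answer(question, profile, rng)
        actions: list[tuple] = [("answer", latency, answer)]
        if rng.random() < profile.undo_prob:
            actions.append(("undo",))
            if rng.random() < profile.undo_abandon_prob:
                actions.append(("timeout",))
            else:
                answer = _sample_answer(question, profile, rng)
                actions.append(("answer", _sample_latency(profile, rng),
                                answer))
                ev.undo_used = True
        elif rng.random() < profile.dismiss_prob:
            actions.append(("swipe", latency + 1.0))
        ev.status = prompt_lifecycle(actions)
        if ev.status == STATUS_ANSWERED:
            ev.answer = answer
            ev.latency_s = latency
        ev.undo_used = ev.undo_used and ev.status == STATUS_ANSWERED
    else:
        if rng.random() < profile.dismiss_prob:
            ev.status = prompt_lifecycle([("swipe", 2.0)])
        else:
            ev.status = prompt_lifecycle([("timeout",)])
    return ev
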