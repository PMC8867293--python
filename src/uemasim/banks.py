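"""Bundled default question banks.

The 30-item core bank mirrors the published composition — 13 internal,
6 external, 6 reflective, 5 reactive — with single-tap wordings and
three-way Yes / Sort of / No answers.  Per-day caps default to 8 for
internal items (fast-moving states), 4 for the other core categories,
and 1 for the once-daily sleep item.

Engagement (280 items) and validation (300 items) banks are generated
programmatically: a handful of realistic wordings followed by templated
fillers, which is sufficient for simulation since only bank *size*
drives the no-repeat horizons.
"""

from __future__ import annotations

from .selection import QuestionSpec

_YSN = ("Yes", "Sort of", "No")
_YN = ("Yes", "No")

_INTERNAL = [
    "Feeling stressed?", "Feeling happy?", "Feeling tired?",
    "Feeling nervous?", "Feeling sad?", "In pain right now?",
    "Feeling energetic?", "Feeling hungry?", "Feeling relaxed?",
    "Feeling focused?", "Feeling irritable?", "Feeling motivated?",
]
_INTERNAL_ONCE = "Slept well last night?"
_EXTERNAL = [
    "With friends right now?", "At work or school?", "Workload heavy today?",
    "Someone urged you to exercise?", "In a noisy place?",
    "Eating with others?",
]
_REFLECTIVE = [
    "Intend to exercise today?", "Planning your meals today?",
    "Trying to sit less today?", "Thinking about health goals?",
    "Intend to sleep on time?", "Considering a walk soon?",
]
_REACTIVE = [
    "On your usual routine?", "Acting out of habit?",
    "Craving a snack?", "Moving without planning to?",
    "Doing your usual commute?",
]


def default_core_bank() -> list[QuestionSpec]:
    """30 core-construct items: 13 internal, 6 external, 6 reflective,
    5 reactive."""
    bank: list[QuestionSpec] = []
    for i, text in enumerate(_INTERNAL, 1):
        bank.append(QuestionSpec(f"int{i:02d}", text, "internal", _YSN,
                                 max_per_day=8))
    bank.append(QuestionSpec("int13", _INTERNAL_ONCE, "internal", _YSN,
                             max_per_day=1))
    for i, text in enumerate(_EXTERNAL, 1):
        bank.append(QuestionSpec(f"ext{i:02d}", text, "external", _YSN,
                                 max_per_day=4))
    for i, text in enumerate(_REFLECTIVE, 1):
        bank.append(QuestionSpec(f"rfl{i:02d}", text, "reflective", _YSN,
                                 max_per_day=4))
    for i, text in enumerate(_REACTIVE, 1):
        bank.append(QuestionSpec(f"rct{i:02d}", text, "reactive", _YSN,
                                 max_per_day=4))
    return bank


def default_engagement_bank(n: int = 280) -> list[QuestionSpec]:
    """Person-level characteristic items that rarely repeat (~3.5 months
    at 5 engagement slots/day for the default 280-item bank)."""
    seeds = [
        ("Own a pet?", _YN),
        ("Bike to work?", ("Frequently", "Sometimes", "Rarely")),
        ("Morning person?", _YSN),
        ("Own a car?", _YN),
        ("Cook most days?", _YSN),
        ("Play a musical instrument?", _YN),
    ]
    bank = [QuestionSpec(f"eng{i + 1:03d}", text, "engagement", opts,
                         max_per_day=1)
            for i, (text, opts) in enumerate(seeds[:n])]
    for i in range(len(bank), n):
        bank.append(QuestionSpec(f"eng{i + 1:03d}",
                                 f"Enjoy hobby #{i + 1}?", "engagement",
                                 _YSN, max_per_day=1))
    return bank


def default_validation_bank(n: int = 300) -> list[QuestionSpec]:
    """Attention-check items with one unambiguously correct answer
    (~7.5 months without repetition at one validation slot/day)."""
    bank: list[QuestionSpec] = []
    fixed = [
        ("Do pigs fly?", _YN, "No"),
        ("Sun rises in the east?", _YN, "Yes"),
        ("Please press A:", ("A", "B", "C"), "A"),
        ("Is ice cold?", _YN, "Yes"),
    ]
    for i, (text, opts, correct) in enumerate(fixed[:n], 1):
        bank.append(QuestionSpec(f"val{i:03d}", text, "validation", opts,
                                 max_per_day=1, correct_answer=correct))
    i = len(bank)
    a = b = 1
    while len(bank) < n:
        i += 1
        a = (a % 9) + 1
        b = (b * 3 % 7) + 1
        wrong = a + b + (1 if i % 2 else -1)
        truth = i % 3 == 0
        s = a + b if truth else wrong
        bank.append(QuestionSpec(
            f"val{i:03d}", f"{a} + {b} = {s}?", "validation", _YN,
            max_per_day=1, correct_answer="Yes" if truth else "No"))
    return bank
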