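"""Question-bank and event-log file I/O.

Question banks are CSV (columns ``id,text,category,answers,max_per_day,
correct_answer`` with pipe-separated answers) or JSON (list of objects
with the same fields).  Event logs are tidy CSV with one row per
scheduled prompt.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path

import pandas as pd

from .metrics import EVENT_COLUMNS
from .selection import QuestionSpec


def read_question_bank(path: str | Path) -> list[QuestionSpec]:
    """Read and validate a question bank from CSV or JSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise ValueError(f"{path}: JSON bank must be a list of objects")
    else:
        try:
            df = pd.read_csv(path, dtype={"id": str})
        except pd.errors.EmptyDataError:
            raise ValueError(f"{path}: empty question-bank file") from None
        records = df.to_dict("records")
    if not records:
        raise ValueError(f"{path}: empty question-bank file")

    bank: list[QuestionSpec] = []
    for rec in records:
        answers = rec.get("answers") or rec.get("answer_options")
        if isinstance(answers, str):
            answers = tuple(a.strip() for a in answers.split("|"))
        else:
            answers = tuple(answers or ())
        correct = rec.get("correct_answer")
        if correct is not None and (pd.isna(correct) or correct == ""):
            correct = None
        bank.append(QuestionSpec(
            id=str(rec["id"]), text=str(rec["text"]),
            category=str(rec["category"]), answer_options=answers,
            max_per_day=int(rec.get("max_per_day", 8) or 8),
            correct_answer=correct))

    dup = [qid for qid, n in Counter(q.id for q in bank).items() if n > 1]
    if dup:
        raise ValueError(f"{path}: duplicate question ids {dup}")
    return bank


def write_question_bank(bank: list[QuestionSpec], path: str | Path) -> None:
    path = Path(path)
    rows = [{"id": q.id, "text": q.text, "category": q.category,
             "answers": "|".join(q.answer_options),
             "max_per_day": q.max_per_day,
             "correct_answer": q.correct_answer or ""}
            for q in bank]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1))
    else:
        pd.DataFrame(rows).to_csv(path, index=False)


def category_counts(bank: list[QuestionSpec]) -> dict[str, int]:
    return dict(Counter(q.category for q in bank))


def write_event_log(events: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in EVENT_COLUMNS if c in events.columns]
    events[cols].to_csv(path, index=False)


def read_event_log(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "prompt_id": str},
                     parse_dates=["timestamp"])
    df["delivered"] = df["delivered"].astype(bool)
    if "undo_used" in df:
        df["undo_used"] = df["undo_used"].fillna(False).astype(bool)
    return df
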