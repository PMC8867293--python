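"""Run configuration, schema-validated with pydantic (unknown keys are
rejected so typos in YAML fail fast)."""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .respondent import RespondentProfile
from .scheduler import CalendarConfig


class SchedulerSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    study_days: int = 7
    start_date: dt.date = dt.date(2021, 1, 4)
    burst_anchor: str = "friday"
    pre_study_days: int = 0
    sleep_time: str = "23:00"
    wake_time: str = "07:00"
    gap_min: float = 8.0
    prompts_per_hour: int = 4

    def to_calendar_config(self, participant_id: str) -> CalendarConfig:
        return CalendarConfig(
            participant_id=participant_id,
            start_date=self.start_date,
            study_days=self.study_days,
            burst_anchor=self.burst_anchor,
            pre_study_days=self.pre_study_days,
            sleep_time=dt.time.fromisoformat(self.sleep_time),
            wake_time=dt.time.fromisoformat(self.wake_time))


class RespondentSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    answer_prob: float = 0.75
    dismiss_prob: float = 0.02
    undo_prob: float = 0.05
    undo_abandon_prob: float = 0.10
    validation_error_rate: float = 0.07
    latency_mu: float = 1.5278
    latency_sigma: float = 0.2856

    def to_profile(self) -> RespondentProfile:
        return RespondentProfile(**self.model_dump())


class SensorSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    enabled: bool = False
    pa_threshold: float = Field(2.67, gt=0)
    sb_threshold: float = Field(2.67, gt=0)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    participant_id: str = "p001"
    seed: int = 0
    question_bank: str | None = None     # path; None = bundled default
    out_dir: str = "."
    #: daily do-not-disturb intervals, minutes from midnight
    dnd_intervals: list[tuple[float, float]] = Field(default_factory=list)
    scheduler: SchedulerSection = Field(default_factory=SchedulerSection)
    respondent: RespondentSection = Field(default_factory=RespondentSection)
    sensor: SensorSection = Field(default_factory=SensorSection)
    verbosity: int = 0


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" \
        else yaml.safe_load(text)
    return RunConfig.model_validate(data or {})
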