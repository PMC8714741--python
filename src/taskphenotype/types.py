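"""Shared domain types for the assessment battery.

The battery consists of three attention tasks (D2 test of attention,
delayed matching to sample, spatial working memory).  A participant's raw
interaction with each task is captured as an :class:`EventLog` — an
ordered, timestamped stream of task-specific events — which the task
modules score into behavioral metrics.  Questionnaire answers travel as
:class:`ScaleResponse` objects attached to a :class:`ParticipantRecord`.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

TaskId = Literal["d2", "dmts", "swm"]

#: Legal event kinds per task. Any other kind in a log is a schema error.
TASK_EVENT_KINDS: dict[str, frozenset[str]] = {
    "d2": frozenset({"page_start", "page_end", "nav_left", "nav_right", "mark"}),
    "dmts": frozenset({"trial_start", "choices_on", "select"}),
    "swm": frozenset({"trial_start", "sequence_start", "open", "token_found"}),
}


class StimulusShape(BaseModel):
    """A form/color combination assigned to a participant and reused
    across all three tasks (notched-and-dotted in D2, pattern background
    in DMTS, search token in SWM)."""

    form_id: int = Field(ge=0)
    color_id: int = Field(ge=0)


class Event(BaseModel):
    """One timestamped interaction. ``t`` is integer milliseconds from
    task onset; ``data`` carries the kind-specific payload (page index,
    choice index, box id, ...)."""

    t: int = Field(ge=0)
    kind: str
    data: dict[str, int] = Field(default_factory=dict)


class EventLog(BaseModel):
    """Ordered interaction record for one participant on one task.

    ``seed`` identifies the task battery the participant saw, so a log
    can be scored without shipping the battery alongside it.
    """

    participant_id: str
    task_id: TaskId
    seed: int
    events: list[Event] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_events(self) -> "EventLog":
        legal = TASK_EVENT_KINDS[self.task_id]
        prev_t = 0
        for i, ev in enumerate(self.events):
            if ev.kind not in legal:
                raise ValueError(
                    f"event {i}: kind {ev.kind!r} not legal for task {self.task_id!r}"
                )
            if ev.t < prev_t:
                raise ValueError(
                    f"event {i}: timestamp {ev.t} decreases (previous {prev_t})"
                )
            prev_t = ev.t
        return self


class ScaleResponse(BaseModel):
    """Answers to one self-report scale plus the time taken to complete
    it (the operand of the response-speed quality filter)."""

    scale_id: str
    item_responses: list[int] = Field(min_length=1)
    completion_time_s: float = Field(gt=0)

    @property
    def seconds_per_item(self) -> float:
        return self.completion_time_s / len(self.item_responses)


class ParticipantRecord(BaseModel):
    """Demographics, scale responses, and up to one event log per task."""

    participant_id: str
    age: int = Field(ge=18)
    gender: Literal["female", "male"]
    scales: list[ScaleResponse] = Field(default_factory=list)
    logs: dict[TaskId, EventLog] = Field(default_factory=dict)

    def scale(self, scale_id: str) -> Optional[ScaleResponse]:
        for s in self.scales:
            if s.scale_id == scale_id:
                return s
        return None


class MetricVector(BaseModel):
    """The 14 behavioral measures for one participant.

    All fields are optional: a participant may have completed only a
    subset of the tasks (missing values serialize as empty CSV cells).
    """

    # D2 test of attention
    d2_n_items: Optional[int] = None
    d2_n_correct: Optional[int] = None
    d2_n_omission: Optional[int] = None
    d2_n_commission: Optional[int] = None
    d2_n_errors: Optional[int] = None
    d2_error_rate: Optional[float] = None
    # Delayed matching to sample
    dmts_n_correct: Optional[int] = None
    dmts_avg_latency_ms: Optional[float] = None
    dmts_n_color_errors: Optional[int] = None
    dmts_n_shape_errors: Optional[int] = None
    dmts_n_both_errors: Optional[int] = None
    # Spatial working memory
    swm_n_between_errors: Optional[int] = None
    swm_n_within_errors: Optional[int] = None
    swm_strategy_score: Optional[int] = None


#: Stable column order for the serialized metrics table.
METRIC_COLUMNS: tuple[str, ...] = tuple(MetricVector.model_fields)
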