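"""Serialization of event logs (JSON-Lines) and cohort/metrics tables (CSV).

Event-log files hold one record per line::

    {"participant_id": "p1", "task_id": "d2", "seed": 7,
     "events": [{"t": 0, "kind": "page_start", "page": 0}, ...]}

Payload fields are flattened into the event object.  Malformed lines are
rejected with errors that name the offending line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd
from pydantic import ValidationError

from .types import METRIC_COLUMNS, Event, EventLog, MetricVector, ParticipantRecord

PathLike = Union[str, Path]


class EventLogParseError(ValueError):
    """A JSON-Lines event-log file failed validation at a specific line."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


def _event_to_json(ev: Event) -> dict:
    out: dict = {"t": ev.t, "kind": ev.kind}
    out.update(ev.data)
    return out


def _event_from_json(obj: Mapping) -> Event:
    data = {k: v for k, v in obj.items() if k not in ("t", "kind")}
    return Event(t=obj["t"], kind=obj["kind"], data=data)


def write_event_logs(logs: Iterable[EventLog], path: PathLike) -> int:
    """Write logs as JSON-Lines; returns the number of records written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for log in logs:
            rec = {
                "participant_id": log.participant_id,
                "task_id": log.task_id,
                "seed": log.seed,
                "events": [_event_to_json(e) for e in log.events],
            }
            fh.write(json.dumps(rec, separators=(",", ":")) + "\n")
            n += 1
    return n


def read_event_logs(path: PathLike) -> list[EventLog]:
    """Read a JSON-Lines event-log file.

    Returns logs in file order.  Raises :class:`EventLogParseError`
    naming the line number for malformed JSON, missing required fields,
    unknown task ids, illegal event kinds, or non-monotone timestamps.
    """
    logs: list[EventLog] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise EventLogParseError(line_no, f"invalid JSON: {exc}") from exc
            for field in ("participant_id", "task_id", "seed", "events"):
                if field not in obj:
                    raise EventLogParseError(line_no, f"missing required field {field!r}")
            try:
                events = [_event_from_json(e) for e in obj["events"]]
                log = EventLog(
                    participant_id=obj["participant_id"],
                    task_id=obj["task_id"],
                    seed=obj["seed"],
                    events=events,
                )
            except (ValidationError, KeyError, TypeError) as exc:
                raise EventLogParseError(line_no, str(exc)) from exc
            logs.append(log)
    return logs


def write_metrics_table(
    records: Iterable[ParticipantRecord],
    metrics: Mapping[str, MetricVector],
    path: PathLike,
) -> int:
    """Write one CSV row per participant: id, age, gender, phq9 total
    (empty if no PHQ-9 scale is attached), then the 14 metric columns in
    the documented stable order.  Returns the number of data rows.

    Raises ``ValueError`` on duplicate participant ids.
    """
    from .phq9 import score_phq9_items

    rows = []
    seen: set[str] = set()
    for rec in records:
        if rec.participant_id in seen:
            raise ValueError(f"duplicate participant_id {rec.participant_id!r}")
        seen.add(rec.participant_id)
        row: dict = {
            "participant_id": rec.participant_id,
            "age": rec.age,
            "gender": rec.gender,
        }
        phq = rec.scale("phq9")
        row["phq9_total"] = (
            score_phq9_items(phq.item_responses[:9]).total if phq is not None else None
        )
        mv = metrics.get(rec.participant_id, MetricVector())
        for col in METRIC_COLUMNS:
            row[col] = getattr(mv, col)
        rows.append(row)
    columns = ["participant_id", "age", "gender", "phq9_total", *METRIC_COLUMNS]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False)
    return len(df)


def read_metrics_table(path: PathLike) -> pd.DataFrame:
    """Read a metrics table written by :func:`write_metrics_table`."""
    return pd.read_csv(path)
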