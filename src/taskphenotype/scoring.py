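"""Participant-level scoring: event logs -> the 14 behavioral measures.

Each log carries the seed of the battery the participant saw, so the
battery is regenerated deterministically and the log scored against it.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd

from .d2 import D2Config, generate_d2_battery, score_d2
from .dmts import DMTSConfig, generate_dmts_battery, score_dmts
from .phq9 import score_phq9_items
from .swm import SWMConfig, generate_swm_battery, score_swm
from .types import METRIC_COLUMNS, EventLog, MetricVector, ParticipantRecord

#: task owning each behavioral measure (used for PCA component attribution)
TASK_OF_MEASURE: dict[str, str] = {
    col: col.split("_", 1)[0] for col in METRIC_COLUMNS
}


def score_log(
    log: EventLog,
    d2_config: Optional[D2Config] = None,
    dmts_config: Optional[DMTSConfig] = None,
    swm_config: Optional[SWMConfig] = None,
):
    """Score one event log against the battery regenerated from its seed."""
    if log.task_id == "d2":
        return score_d2(log, generate_d2_battery(log.seed, d2_config))
    if log.task_id == "dmts":
        return score_dmts(log, generate_dmts_battery(log.seed, config=dmts_config))
    return score_swm(log, generate_swm_battery(log.seed, swm_config), swm_config)


def score_participant(record: ParticipantRecord, **configs) -> MetricVector:
    """Score whichever task logs the participant has into a
    :class:`MetricVector`; tasks without a log stay missing."""
    fields: dict = {}
    for task_id, log in record.logs.items():
        metrics = score_log(log, **configs)
        prefix = f"{task_id}_"
        for name, value in metrics.model_dump().items():
            fields[prefix + name] = value
    return MetricVector(**fields)


def cohort_metrics_frame(
    records: Sequence[ParticipantRecord], **configs
) -> pd.DataFrame:
    """Score a cohort into the analysis table: participant_id, age,
    gender, phq9_total, and the 14 metric columns."""
    rows = []
    for rec in records:
        mv = score_participant(rec, **configs)
        phq = rec.scale("phq9")
        row = {
            "participant_id": rec.participant_id,
            "age": rec.age,
            "gender": rec.gender,
            "phq9_total": (
                score_phq9_items(phq.item_responses[:9]).total if phq else None
            ),
        }
        row.update(mv.model_dump())
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["participant_id", "age", "gender", "phq9_total", *METRIC_COLUMNS]
    )
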