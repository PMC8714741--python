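"""Careless-responding filters for online cohorts.

Data gathered remotely must be screened for participants who did not
engage (random clicking, straight-lining) and for bots.  Three
scale-level screens are applied, and a participant is removed when ANY
one of them flags more than two of their scales:

* **speed** — a scale completed in under one second per item;
* **zero variance** — the same response repeated on every item;
* **outlier variance** — a response variance more than three standard
  deviations above the cohort's mean variance for that scale.

Thresholds for the outlier-variance screen are computed once on the
full original cohort (no iterative re-filtering), with sample (n-1)
variances and SDs throughout.  Flag comparisons are strict: exactly two
flagged scales keeps the participant.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field

from .types import ParticipantRecord, ScaleResponse

FLAG_LIMIT = 2  # removal requires strictly more flagged scales than this


class FilterReport(BaseModel):
    participant_id: str
    speed_flags: int = Field(ge=0)
    zero_variance_flags: int = Field(ge=0)
    outlier_variance_flags: int = Field(ge=0)
    removed: bool
    reasons: list[str] = Field(default_factory=list)


def speed_filter(scales: Sequence[ScaleResponse]) -> int:
    """Number of scales completed in under 1 s per item (strict)."""
    count = 0
    for s in scales:
        if len(s.item_responses) == 0:
            raise ValueError(f"scale {s.scale_id!r} has no items")
        if s.seconds_per_item < 1.0:
            count += 1
    return count


def zero_variance_filter(scales: Sequence[ScaleResponse]) -> int:
    """Number of scales whose responses are all identical.  A one-item
    scale is degenerately flagged; configurations should exclude such
    scales from filtering."""
    return sum(1 for s in scales if len(set(s.item_responses)) == 1)


def outlier_variance_filter(
    cohort_scales: Sequence[Sequence[ScaleResponse]],
) -> list[int]:
    """Per-participant count of scales whose response variance exceeds
    the cohort mean variance for that scale by more than three SDs.

    ``cohort_scales`` is one scale list per participant; scales are
    aligned across participants by ``scale_id``.  Thresholds use the
    sample (n-1) variance of each participant's responses and the
    sample SD of those variances over the cohort.  The comparison is
    strict, so a cohort of identical variances flags nobody.
    """
    if len(cohort_scales) < 3:
        raise ValueError("outlier variance filter needs at least 3 participants")

    by_scale: dict[str, list[tuple[int, float]]] = {}
    for p_idx, scales in enumerate(cohort_scales):
        for s in scales:
            var = float(np.var(s.item_responses, ddof=1)) if len(s.item_responses) > 1 else 0.0
            by_scale.setdefault(s.scale_id, []).append((p_idx, var))

    flags = [0] * len(cohort_scales)
    for variances in by_scale.values():
        vals = np.array([v for _, v in variances])
        mean = vals.mean()
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        threshold = mean + 3.0 * sd
        for p_idx, v in variances:
            if v > threshold:
                flags[p_idx] += 1
    return flags


def apply_filters(
    cohort: Sequence[ParticipantRecord],
) -> tuple[list[ParticipantRecord], list[FilterReport]]:
    """Apply all three screens to a cohort in a single pass.

    Returns the kept participants and one report per original
    participant.  A participant is removed iff any screen flags more
    than :data:`FLAG_LIMIT` of their scales.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    outlier_flags = outlier_variance_filter([p.scales for p in cohort])

    kept: list[ParticipantRecord] = []
    reports: list[FilterReport] = []
    for rec, n_outlier in zip(cohort, outlier_flags):
        n_speed = speed_filter(rec.scales)
        n_zero = zero_variance_filter(rec.scales)
        reasons = []
        if n_speed > FLAG_LIMIT:
            reasons.append("speed")
        if n_zero > FLAG_LIMIT:
            reasons.append("zero_variance")
        if n_outlier > FLAG_LIMIT:
            reasons.append("outlier_variance")
        removed = bool(reasons)
        reports.append(
            FilterReport(
                participant_id=rec.participant_id,
                speed_flags=n_speed,
                zero_variance_flags=n_zero,
                outlier_variance_flags=n_outlier,
                removed=removed,
                reasons=reasons,
            )
        )
        if not removed:
            kept.append(rec)
    return kept, reports
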