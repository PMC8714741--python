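"""PHQ-9 scoring.

The 9-item Patient Health Questionnaire depression module: each item is
rated 0-3 for symptom frequency over the past two weeks, the total (0-27)
is the severity measure, and standard Kroenke cut-points band the total
into five severity levels.  The optional tenth "difficulty" item is
stored but never scored.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator

Phq9Level = Literal["minimal", "mild", "moderate", "moderately severe", "severe"]

#: (upper bound inclusive, level) — the standard Kroenke bands.
_LEVEL_BANDS: tuple[tuple[int, Phq9Level], ...] = (
    (4, "minimal"),
    (9, "mild"),
    (14, "moderate"),
    (19, "moderately severe"),
    (27, "severe"),
)


class Phq9Response(BaseModel):
    items: list[int] = Field(min_length=9, max_length=9)
    difficulty_item: Optional[int] = None  # collected, never scored

    @field_validator("items")
    @classmethod
    def _items_in_range(cls, v: list[int]) -> list[int]:
        for i, item in enumerate(v):
            if not 0 <= item <= 3:
                raise ValueError(f"item {i + 1} = {item} outside 0-3")
        return v


class Phq9Score(BaseModel):
    total: int = Field(ge=0, le=27)
    level: Phq9Level


def phq9_level(total: int) -> Phq9Level:
    """Map a PHQ-9 total to its severity level (Kroenke cut-points:
    0-4 minimal, 5-9 mild, 10-14 moderate, 15-19 moderately severe,
    20-27 severe)."""
    if not 0 <= total <= 27:
        raise ValueError(f"PHQ-9 total {total} outside 0-27")
    for upper, level in _LEVEL_BANDS:
        if total <= upper:
            return level
    raise AssertionError("unreachable")


def score_phq9(response: Phq9Response) -> Phq9Score:
    """Total = item sum; level via :func:`phq9_level`."""
    total = sum(response.items)
    return Phq9Score(total=total, level=phq9_level(total))


def score_phq9_items(items: list[int]) -> Phq9Score:
    """Convenience wrapper: score a bare 9-item list."""
    return score_phq9(Phq9Response(items=items))
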