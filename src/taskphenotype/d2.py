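"""D2 test of attention: page generation and event-log scoring.

Each page is a 7x6 grid of 42 hard-to-distinguish stimuli built from the
participant's assigned shape: a notch on the left or right and 1-4 dots.
The target is defined as "2 dots and a notch on the left"; every other
item is a distractor of one of three classes (correct notch / wrong
dots, wrong notch / correct dots, wrong notch and dots).  Participants
step through items with arrow keys and mark presumed targets; there are
20 timed pages per assessment.

Scoring follows the classic paper-form convention: omissions are
unmarked targets within the processed range, commissions are marked
non-targets, and the per-page processed count is one plus the furthest
item the cursor reached (backtracking never reduces it).  The error
rate is expressed per 100 processed items.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .types import EventLog

TARGET_DOTS = 2
ITEMS_PER_PAGE = 42  # 7 columns x 6 rows
N_PAGES = 20

NotchSide = Literal["left", "right"]

#: distractor classes: (notch correct?, dots correct?)
DISTRACTOR_CLASSES = ("good_notch_bad_dots", "bad_notch_good_dots", "bad_notch_bad_dots")


class D2Config(BaseModel):
    """Page-composition parameters.

    ``target_proportion`` defaults to 0.45, approximately the target
    density of the classic pen-and-paper form; the remaining items are
    split across the three distractor classes by ``distractor_mix``
    (must sum to 1), any integer remainder assigned by seeded draw.
    """

    n_pages: int = Field(default=N_PAGES, ge=1)
    target_proportion: float = Field(default=0.45, gt=0, lt=1)
    distractor_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    @model_validator(mode="after")
    def _mix_sums_to_one(self) -> "D2Config":
        if abs(sum(self.distractor_mix) - 1.0) > 1e-9:
            raise ValueError("distractor_mix proportions must sum to 1")
        return self


class D2Item(BaseModel):
    index: int = Field(ge=0, lt=ITEMS_PER_PAGE)
    dots: int = Field(ge=1, le=4)
    notch_side: NotchSide

    @property
    def is_target(self) -> bool:
        return self.dots == TARGET_DOTS and self.notch_side == "left"


class D2PageSpec(BaseModel):
    page_index: int = Field(ge=0)
    items: list[D2Item] = Field(min_length=ITEMS_PER_PAGE, max_length=ITEMS_PER_PAGE)


class D2Metrics(BaseModel):
    """The six D2 measures, summed over the 20 pages."""

    n_items: int = Field(ge=0)
    n_correct: int = Field(ge=0)
    n_omission: int = Field(ge=0)
    n_commission: int = Field(ge=0)
    n_errors: int = Field(ge=0)
    error_rate: float = Field(ge=0, le=100)


def _make_item(index: int, category: str, rng: np.random.Generator) -> D2Item:
    wrong_dots = lambda: int(rng.choice([1, 3, 4]))  # noqa: E731
    if category == "target":
        return D2Item(index=index, dots=TARGET_DOTS, notch_side="left")
    if category == "good_notch_bad_dots":
        return D2Item(index=index, dots=wrong_dots(), notch_side="left")
    if category == "bad_notch_good_dots":
        return D2Item(index=index, dots=TARGET_DOTS, notch_side="right")
    return D2Item(index=index, dots=wrong_dots(), notch_side="right")


def generate_d2_battery(seed: int, config: D2Config | None = None) -> list[D2PageSpec]:
    """Generate the page specifications for one assessment, deterministic
    in ``seed``.  Per-page target count is ``round(42 * target_proportion)``."""
    config = config or D2Config()
    rng = np.random.default_rng(seed)
    n_targets = round(ITEMS_PER_PAGE * config.target_proportion)
    n_distract = ITEMS_PER_PAGE - n_targets
    base = [int(np.floor(p * n_distract)) for p in config.distractor_mix]
    pages = []
    for page_index in range(config.n_pages):
        counts = list(base)
        # remainder distractors to random classes
        for _ in range(n_distract - sum(counts)):
            counts[int(rng.integers(3))] += 1
        categories = ["target"] * n_targets
        for cls, c in zip(DISTRACTOR_CLASSES, counts):
            categories.extend([cls] * c)
        order = rng.permutation(ITEMS_PER_PAGE)
        placed = [""] * ITEMS_PER_PAGE
        for slot, cat in zip(order, categories):
            placed[slot] = cat
        items = [_make_item(i, cat, rng) for i, cat in enumerate(placed)]
        pages.append(D2PageSpec(page_index=page_index, items=items))
    return pages


def d2_error_rate(n_errors: int, n_items: int) -> float:
    """Errors per 100 processed items; 0 for an empty assessment."""
    if n_items < 0:
        raise ValueError("n_items must be non-negative")
    if n_items == 0:
        return 0.0
    return 100.0 * n_errors / n_items


def score_d2(log: EventLog, battery: Sequence[D2PageSpec]) -> D2Metrics:
    """Score a D2 event log against its battery.

    The cursor starts at item 0 on ``page_start`` and moves with
    ``nav_left``/``nav_right`` (clamped to the grid); ``mark`` marks the
    item under the cursor (idempotent).  A page's processed range is
    items 0..max index visited; unvisited pages contribute nothing.
    """
    if log.task_id != "d2":
        raise ValueError(f"expected a d2 log, got {log.task_id!r}")

    # marked positions and furthest cursor per page
    page_state: dict[int, tuple[int, set[int]]] = {}
    page: int | None = None
    cursor = 0
    max_idx = 0
    marked: set[int] = set()

    def _flush() -> None:
        if page is not None:
            prev_max, prev_marked = page_state.get(page, (0, set()))
            page_state[page] = (max(prev_max, max_idx), prev_marked | marked)

    for i, ev in enumerate(log.events):
        if ev.kind == "page_start":
            _flush()
            page = ev.data.get("page", len(page_state))
            if not 0 <= page < len(battery):
                raise ValueError(f"event {i}: page index {page} out of range")
            cursor = 0
            max_idx = 0
            marked = set()
        elif ev.kind == "nav_right":
            cursor = min(cursor + 1, ITEMS_PER_PAGE - 1)
            max_idx = max(max_idx, cursor)
        elif ev.kind == "nav_left":
            cursor = max(cursor - 1, 0)
        elif ev.kind == "mark":
            if page is None:
                raise ValueError(f"event {i}: mark with no current cursor position")
            marked.add(cursor)
        elif ev.kind == "page_end":
            _flush()
            page = None
    _flush()

    n_items = n_correct = n_omission = n_commission = 0
    for page_index, (mx, mk) in page_state.items():
        items = battery[page_index].items
        processed = mx + 1
        n_items += processed
        for idx in range(processed):
            if items[idx].is_target:
                if idx in mk:
                    n_correct += 1
                else:
                    n_omission += 1
            elif idx in mk:
                n_commission += 1

    n_errors = n_omission + n_commission
    return D2Metrics(
        n_items=n_items,
        n_correct=n_correct,
        n_omission=n_omission,
        n_commission=n_commission,
        n_errors=n_errors,
        error_rate=d2_error_rate(n_errors, n_items),
    )
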