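"""Spatial working memory task: trial generation and scoring.

A trial presents ``n`` boxes; the participant searches for a hidden
token over ``n`` sequences, one token per box per trial, and a box that
has yielded a token is never used again.  Box positions are re-drawn
every trial to discourage stereotyped search.  Difficulty levels use 4,
6, 8, 10, 12 and 14 boxes, one trial each.

Measures: a *within* search error is any re-opening of a box already
opened in the current sequence; a *between* search error is any opening
of a box already emptied earlier in the same trial (a single open can be
both); the *strategy score* is, per trial, the number of distinct boxes
used to begin sequences, summed over the six trials (lower = more
systematic search).

Token placement is uniform among the not-yet-emptied boxes at each
sequence start; the adversarial placement of the classic clinical
battery is deliberately not emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .types import EventLog

BOX_LEVELS = (4, 6, 8, 10, 12, 14)


@dataclass
class SWMTrialState:
    """Mutable search state used during token placement."""

    n_boxes: int
    emptied: set[int] = field(default_factory=set)


class SWMConfig(BaseModel):
    box_levels: tuple[int, ...] = BOX_LEVELS
    #: when True (default) an open that re-visits an emptied box already
    #: opened this sequence increments both error counters
    double_count_overlap: bool = True


class SWMTrialSpec(BaseModel):
    trial_index: int = Field(ge=0)
    n_boxes: int = Field(ge=1)
    #: cosmetic layout coordinates in the unit square; never scored
    box_positions: list[tuple[float, float]]
    #: token_schedule[s] = box holding the token during sequence s
    token_schedule: list[int]

    @model_validator(mode="after")
    def _schedule_is_permutation(self) -> "SWMTrialSpec":
        if sorted(self.token_schedule) != list(range(self.n_boxes)):
            raise ValueError("token_schedule must be a permutation of box ids")
        return self


class SWMMetrics(BaseModel):
    """Between/within search errors and the strategy score, summed over
    the six trials."""

    n_between_errors: int = Field(ge=0)
    n_within_errors: int = Field(ge=0)
    strategy_score: int = Field(ge=0)


def place_token(trial_state: SWMTrialState, rng: np.random.Generator) -> int:
    """Uniform seeded draw among the not-yet-emptied boxes."""
    candidates = [b for b in range(trial_state.n_boxes) if b not in trial_state.emptied]
    if not candidates:
        raise ValueError("no non-emptied boxes remain")
    return int(rng.choice(candidates))


def generate_swm_battery(seed: int, config: SWMConfig | None = None) -> list[SWMTrialSpec]:
    """One trial per difficulty level, ascending, deterministic in
    ``seed``.  Each trial's token schedule is built by drawing the token
    uniformly among non-emptied boxes at each sequence start, which
    makes it a permutation of the box ids."""
    config = config or SWMConfig()
    rng = np.random.default_rng(seed)
    trials = []
    for trial_index, n_boxes in enumerate(config.box_levels):
        positions = [(float(x), float(y)) for x, y in rng.random((n_boxes, 2))]
        state = SWMTrialState(n_boxes=n_boxes)
        schedule = []
        for _ in range(n_boxes):
            box = place_token(state, rng)
            schedule.append(box)
            state.emptied.add(box)
        trials.append(
            SWMTrialSpec(
                trial_index=trial_index,
                n_boxes=n_boxes,
                box_positions=positions,
                token_schedule=schedule,
            )
        )
    return trials


def score_swm(
    log: EventLog, battery: Sequence[SWMTrialSpec], config: SWMConfig | None = None
) -> SWMMetrics:
    """Score an SWM event log against its battery.

    Every sequence in the log must end with ``token_found`` at the
    scheduled box; ``open`` events of unknown boxes or a ``token_found``
    at the wrong box are errors.
    """
    if log.task_id != "swm":
        raise ValueError(f"expected an swm log, got {log.task_id!r}")
    config = config or SWMConfig()

    n_between = 0
    n_within = 0
    strategy = 0

    trial: int | None = None
    sequence = -1
    emptied: set[int] = set()
    opened_this_seq: set[int] = set()
    seq_starts: set[int] = set()
    last_open: int | None = None

    def _flush_trial() -> None:
        nonlocal strategy
        if trial is not None:
            strategy += len(seq_starts)

    for i, ev in enumerate(log.events):
        if ev.kind == "trial_start":
            _flush_trial()
            trial = ev.data.get("trial", 0)
            if not 0 <= trial < len(battery):
                raise ValueError(f"event {i}: trial index {trial} out of range")
            sequence = -1
            emptied = set()
            seq_starts = set()
            opened_this_seq = set()
        elif ev.kind == "sequence_start":
            sequence = ev.data.get("sequence", sequence + 1)
            opened_this_seq = set()
            last_open = None
        elif ev.kind == "open":
            if trial is None or sequence < 0:
                raise ValueError(f"event {i}: open outside a sequence")
            box = ev.data["box_id"]
            if not 0 <= box < battery[trial].n_boxes:
                raise ValueError(f"event {i}: unknown box_id {box}")
            is_within = box in opened_this_seq
            is_between = box in emptied
            if is_within:
                n_within += 1
            if is_between and (config.double_count_overlap or not is_within):
                n_between += 1
            if not opened_this_seq:
                seq_starts.add(box)
            opened_this_seq.add(box)
            last_open = box
        elif ev.kind == "token_found":
            if trial is None or sequence < 0 or last_open is None:
                raise ValueError(f"event {i}: token_found before any open")
            scheduled = battery[trial].token_schedule[sequence]
            if last_open != scheduled:
                raise ValueError(
                    f"event {i}: token_found at box {last_open}, "
                    f"but sequence {sequence} hides it in box {scheduled}"
                )
            emptied.add(last_open)
    _flush_trial()

    return SWMMetrics(
        n_between_errors=n_between, n_within_errors=n_within, strategy_score=strategy
    )
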