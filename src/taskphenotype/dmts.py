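"""Delayed matching to sample: trial generation and scoring.

Each trial shows a prompt — a 4-quadrant abstract pattern, one color and
one form per quadrant — for 4.5 s, then after a delay of 0, 1, 4 or 12 s
presents four choice patterns: the exact match, a novel distractor
(new colors and new forms), a color distractor (the prompt's forms with
the novel distractor's colors) and a shape distractor (the prompt's
colors with the novel distractor's forms).  All four choices share one
random quadrant with the prompt, which defeats single-quadrant mnemonic
strategies.  Ten trials are run at each delay (40 in total).

Only the first selection of a trial is scored (the forced continuation
until the match is chosen is logged but not scored): the four first-
selection outcomes — correct, color error, shape error, color+shape
("unrelated") error — partition the 40 trials exactly.
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .types import EventLog, StimulusShape

DELAYS_MS = (0, 1000, 4000, 12000)
PROMPT_DURATION_MS = 4500
N_PER_DELAY = 10

ChoiceRole = Literal["match", "color_distractor", "shape_distractor", "novel_distractor"]
Outcome = Literal["correct", "color_error", "shape_error", "both_error"]

_ROLE_OUTCOME: dict[str, Outcome] = {
    "match": "correct",
    "color_distractor": "color_error",
    "shape_distractor": "shape_error",
    "novel_distractor": "both_error",
}


class DMTSConfig(BaseModel):
    n_per_delay: int = Field(default=N_PER_DELAY, ge=1)
    delays_ms: tuple[int, ...] = DELAYS_MS
    prompt_duration_ms: int = PROMPT_DURATION_MS
    n_colors: int = Field(default=8, ge=8)
    n_forms: int = Field(default=8, ge=8)
    #: "interleaved" shuffles delays across the session; "blocked" runs
    #: each delay level as a contiguous block.
    trial_order: Literal["interleaved", "blocked"] = "interleaved"


class QuadPattern(BaseModel):
    """Four (color_id, form_id) pairs, one per quadrant."""

    quadrants: list[tuple[int, int]] = Field(min_length=4, max_length=4)


class DMTSTrialSpec(BaseModel):
    trial_index: int = Field(ge=0)
    delay_ms: int
    prompt_duration_ms: int = PROMPT_DURATION_MS
    prompt: QuadPattern
    #: choices in display order
    choices: list[QuadPattern] = Field(min_length=4, max_length=4)
    #: role of each displayed choice, aligned with ``choices``
    roles: list[ChoiceRole] = Field(min_length=4, max_length=4)
    shared_quadrant: int = Field(ge=0, le=3)

    @model_validator(mode="after")
    def _roles_complete(self) -> "DMTSTrialSpec":
        if set(self.roles) != set(_ROLE_OUTCOME):
            raise ValueError("roles must be a permutation of the four choice roles")
        return self

    @property
    def match_position(self) -> int:
        return self.roles.index("match")


class DMTSMetrics(BaseModel):
    """The five DMTS measures, summed/averaged over the 40 trials."""

    n_correct: int = Field(ge=0)
    avg_latency_ms: float = Field(ge=0)
    n_color_errors: int = Field(ge=0)
    n_shape_errors: int = Field(ge=0)
    n_both_errors: int = Field(ge=0)


def classify_selection(choice_role: str) -> Outcome:
    """Map the role of a selected choice to its scored outcome."""
    try:
        return _ROLE_OUTCOME[choice_role]
    except KeyError:
        raise ValueError(f"unknown choice role {choice_role!r}") from None


def _build_trial(
    trial_index: int, delay_ms: int, config: DMTSConfig, rng: np.random.Generator
) -> DMTSTrialSpec:
    # Prompt uses 4 distinct colors and 4 distinct forms; novel
    # colors/forms for the 3 non-shared quadrants are drawn without
    # replacement from the palette members the prompt did not use.
    prompt_colors = rng.choice(config.n_colors, size=4, replace=False)
    prompt_forms = rng.choice(config.n_forms, size=4, replace=False)
    free_colors = [c for c in range(config.n_colors) if c not in prompt_colors]
    free_forms = [f for f in range(config.n_forms) if f not in prompt_forms]
    if len(free_colors) < 3 or len(free_forms) < 3:
        raise ValueError("palette exhausted: need >= 3 unused colors and forms")
    novel_colors = rng.choice(free_colors, size=3, replace=False)
    novel_forms = rng.choice(free_forms, size=3, replace=False)

    shared = int(rng.integers(4))
    prompt_q = [(int(c), int(f)) for c, f in zip(prompt_colors, prompt_forms)]

    def build(role: str) -> QuadPattern:
        quads = []
        j = 0
        for q in range(4):
            pc, pf = prompt_q[q]
            if q == shared or role == "match":
                quads.append((pc, pf))
            else:
                nc, nf = int(novel_colors[j]), int(novel_forms[j])
                if role == "novel_distractor":
                    quads.append((nc, nf))
                elif role == "color_distractor":  # prompt forms, novel colors
                    quads.append((nc, pf))
                else:  # shape_distractor: prompt colors, novel forms
                    quads.append((pc, nf))
                j += 1
        return QuadPattern(quadrants=quads)

    roles_in_order = ["match", "color_distractor", "shape_distractor", "novel_distractor"]
    patterns = {r: build(r) for r in roles_in_order}
    display = [roles_in_order[k] for k in rng.permutation(4)]
    return DMTSTrialSpec(
        trial_index=trial_index,
        delay_ms=delay_ms,
        prompt_duration_ms=config.prompt_duration_ms,
        prompt=patterns["match"],
        choices=[patterns[r] for r in display],
        roles=display,
        shared_quadrant=shared,
    )


def generate_dmts_battery(
    seed: int,
    assigned_shape: Optional[StimulusShape] = None,
    config: DMTSConfig | None = None,
) -> list[DMTSTrialSpec]:
    """Generate the trial sequence for one assessment, deterministic in
    ``seed``: ``n_per_delay`` trials at each delay, interleaved in
    seeded random order by default.  ``assigned_shape`` is the
    participant's session shape (cosmetic background; not scored)."""
    config = config or DMTSConfig()
    rng = np.random.default_rng(seed)
    delays = [d for d in config.delays_ms for _ in range(config.n_per_delay)]
    if config.trial_order == "interleaved":
        delays = [delays[k] for k in rng.permutation(len(delays))]
    return [_build_trial(i, d, config, rng) for i, d in enumerate(delays)]


def score_dmts(log: EventLog, battery: Sequence[DMTSTrialSpec]) -> DMTSMetrics:
    """Score a DMTS event log against its battery.

    The outcome of a trial is the classification of its FIRST selection;
    its latency is first-selection time minus choices-on time.  Latency
    is averaged over all scored trials, correct and error alike.
    """
    if log.task_id != "dmts":
        raise ValueError(f"expected a dmts log, got {log.task_id!r}")

    counts = {"correct": 0, "color_error": 0, "shape_error": 0, "both_error": 0}
    latencies: list[int] = []
    trial: int | None = None
    t_on: int | None = None
    first_done = False
    match_found = False
    had_selection = False

    def _end_trial(i: int) -> None:
        if trial is not None and not had_selection:
            raise ValueError(f"event {i}: trial {trial} has no selections")

    for i, ev in enumerate(log.events):
        if ev.kind == "trial_start":
            _end_trial(i)
            trial = ev.data.get("trial", 0)
            if not 0 <= trial < len(battery):
                raise ValueError(f"event {i}: trial index {trial} out of range")
            t_on = None
            first_done = False
            match_found = False
            had_selection = False
        elif ev.kind == "choices_on":
            t_on = ev.t
        elif ev.kind == "select":
            if trial is None or t_on is None:
                raise ValueError(f"event {i}: selection before choices_on")
            if match_found:
                raise ValueError(f"event {i}: selection after match already chosen")
            had_selection = True
            choice = ev.data["choice_index"]
            role = battery[trial].roles[choice]
            if not first_done:
                counts[classify_selection(role)] += 1
                latencies.append(ev.t - t_on)
                first_done = True
            if role == "match":
                match_found = True
    _end_trial(len(log.events))

    return DMTSMetrics(
        n_correct=counts["correct"],
        avg_latency_ms=float(np.mean(latencies)) if latencies else 0.0,
        n_color_errors=counts["color_error"],
        n_shape_errors=counts["shape_error"],
        n_both_errors=counts["both_error"],
    )
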