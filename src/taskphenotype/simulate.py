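"""Generative participant model for end-to-end pipeline testing.

A latent depression severity (standard-normal across the cohort) drives
both questionnaire answers and task behavior:

* PHQ-9 items follow a graded-response model whose category thresholds
  shift down as severity rises, so the expected total is strictly
  increasing in severity;
* task-error propensities (D2 omission/commission lapses, DMTS memory
  fidelity and its decay with delay, SWM search-memory failures and
  strategy discipline) are monotone logistic functions of severity with
  per-participant heterogeneity.

Agents play the generated batteries by the tasks' rules — D2 pages
within the 15 s limit, DMTS selections forced to continue until the
match, SWM sequences until the token — so every simulated log satisfies
the scorers' preconditions.  Optional planted careless responders
(speeders, straight-liners, random clickers) violate the quality
filters on three or more scales for filter-recovery tests.

The behavioral model is a test harness, not a cognitive theory; its
default constants are calibrated so cohort-level metric means and SDs
land near the validation study's descriptives, and they live in
:class:`SimConfig`, not in code.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import reference
from .d2 import D2Config, D2PageSpec, generate_d2_battery
from .dmts import DMTSConfig, DMTSTrialSpec, generate_dmts_battery
from .phq9 import Phq9Response
from .swm import SWMConfig, SWMTrialSpec, generate_swm_battery
from .types import Event, EventLog, ParticipantRecord, ScaleResponse


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


CarelessStyle = Literal["speeder", "straightliner", "random_clicker"]

#: auxiliary self-report scales included alongside the PHQ-9:
#: scale_id -> (n_items, max_response)
AUX_SCALES: dict[str, tuple[int, int]] = {
    "anxiety": (7, 3),
    "affect": (10, 4),
    "sleep": (8, 3),
}


class SimConfig(BaseModel):
    """Cohort-simulation parameters.

    Severity is standard normal by default; each behavioral parameter
    is logistic in (base + slope * severity + individual noise).  The
    defaults emulate the validation study's second cohort: n = 90,
    age ~ N(37.9, 11.2) truncated to [18, 72], 63% male.
    """

    model_config = ConfigDict(extra="forbid")

    n: int = Field(default=90, ge=1)
    severity_mean: float = 0.0
    severity_sd: float = 1.0
    age_mean: float = reference.STUDY2_AGE_MEAN
    age_sd: float = reference.STUDY2_AGE_SD
    age_range: tuple[int, int] = (18, 72)
    p_male: float = reference.STUDY2_MALE_PROPORTION
    careless_fraction: float = Field(default=0.0, ge=0, le=1)

    # PHQ-9 graded-response model
    phq9_discrimination: float = 2.0
    phq9_thresholds: tuple[float, float, float] = (0.55, 2.0, 3.3)
    phq9_item_scatter: float = 0.3
    phq9_seconds_per_item: float = 3.0

    # D2: pace (items per page) and lapse propensities
    d2_pace_mean: float = 21.0
    d2_pace_sd: float = 4.5
    d2_omission_base: float = -2.6
    d2_omission_slope: float = 0.45
    d2_omission_scatter: float = 1.0
    d2_commission_base: float = -3.4
    d2_commission_slope: float = 0.5
    d2_commission_scatter: float = 1.7

    # DMTS: memory fidelity logistic in (base - decay*delay_s), error mix
    dmts_memory_base: float = 2.2
    dmts_memory_slope: float = -0.5  # fidelity falls with severity
    dmts_memory_scatter: float = 0.8
    dmts_delay_decay: float = 0.09  # logit units per second of delay
    dmts_error_weights: tuple[float, float, float] = (0.23, 0.58, 0.19)
    dmts_latency_log_mean: float = 8.05  # ln ms; e^8 ~ 3 s
    dmts_latency_log_sd: float = 0.5

    # SWM: per-open error propensities and strategy discipline.  The two
    # per-step error probabilities are jointly capped (swm_error_cap) so a
    # search sequence cannot degenerate into an endless revisit loop.
    swm_between_base: float = -0.2
    swm_between_slope: float = 0.25
    swm_between_scatter: float = 0.6
    swm_within_base: float = -3.0
    swm_within_slope: float = 0.6
    swm_within_scatter: float = 1.4
    swm_error_cap: float = 0.65
    swm_discipline_base: float = -2.8
    swm_discipline_slope: float = -0.6
    swm_discipline_scatter: float = 1.6
    # preference for starting a sequence at a box not yet used as a start
    swm_novelty_base: float = 0.6
    swm_novelty_slope: float = 0.6
    swm_novelty_scatter: float = 1.6

    # task generation configs
    d2: D2Config = Field(default_factory=D2Config)
    dmts: DMTSConfig = Field(default_factory=DMTSConfig)
    swm: SWMConfig = Field(default_factory=SWMConfig)


class ParticipantProfile(BaseModel):
    """Realized behavioral parameters for one simulated participant."""

    participant_id: str
    severity: float
    age: int
    gender: Literal["female", "male"]
    careless: Optional[CarelessStyle] = None

    d2_pace: float = Field(gt=0)
    d2_p_omission: float = Field(ge=0, le=1)
    d2_p_commission: float = Field(ge=0, le=1)
    dmts_memory_logit: float
    dmts_delay_decay: float = Field(ge=0)
    dmts_error_weights: tuple[float, float, float]
    dmts_latency_log_mean: float
    dmts_latency_log_sd: float = Field(ge=0)
    swm_p_between: float = Field(ge=0, le=1)
    swm_p_within: float = Field(ge=0, le=1)
    swm_discipline: float = Field(ge=0, le=1)
    swm_novelty: float = Field(default=0.5, ge=0, le=1)

    def memory_fidelity(self, delay_ms: int) -> float:
        """Probability of a correct DMTS first selection at a delay;
        non-increasing in delay."""
        return _sigmoid(self.dmts_memory_logit - self.dmts_delay_decay * delay_ms / 1000.0)


def _cap_swm_probs(p_between: float, p_within: float, cap: float) -> tuple[float, float]:
    """Scale the two per-step error probabilities proportionally so
    their sum stays below ``cap`` (keeps search sequences finite without
    distorting their severity links)."""
    total = p_between + p_within
    if total > cap:
        scale = cap / total
        return p_between * scale, p_within * scale
    return p_between, p_within


def make_profile(
    participant_id: str,
    severity: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> ParticipantProfile:
    """Draw demographics and severity-linked behavioral parameters."""
    age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)), *config.age_range))
    gender = "male" if rng.random() < config.p_male else "female"

    def logit_param(base: float, slope: float, scatter: float) -> float:
        return _sigmoid(base + slope * severity + scatter * rng.normal())

    return ParticipantProfile(
        participant_id=participant_id,
        severity=severity,
        age=age,
        gender=gender,
        d2_pace=float(np.clip(rng.normal(config.d2_pace_mean, config.d2_pace_sd), 5, 42)),
        d2_p_omission=logit_param(
            config.d2_omission_base, config.d2_omission_slope, config.d2_omission_scatter
        ),
        d2_p_commission=logit_param(
            config.d2_commission_base, config.d2_commission_slope, config.d2_commission_scatter
        ),
        dmts_memory_logit=config.dmts_memory_base
        + config.dmts_memory_slope * severity
        + config.dmts_memory_scatter * rng.normal(),
        dmts_delay_decay=config.dmts_delay_decay,
        dmts_error_weights=config.dmts_error_weights,
        dmts_latency_log_mean=config.dmts_latency_log_mean + 0.1 * rng.normal(),
        dmts_latency_log_sd=config.dmts_latency_log_sd,
        swm_p_between=(swm_probs := _cap_swm_probs(
            logit_param(
                config.swm_between_base, config.swm_between_slope, config.swm_between_scatter
            ),
            logit_param(
                config.swm_within_base, config.swm_within_slope, config.swm_within_scatter
            ),
            config.swm_error_cap,
        ))[0],
        swm_p_within=swm_probs[1],
        swm_discipline=logit_param(
            config.swm_discipline_base, config.swm_discipline_slope, config.swm_discipline_scatter
        ),
        swm_novelty=logit_param(
            config.swm_novelty_base, config.swm_novelty_slope, config.swm_novelty_scatter
        ),
    )


def perfect_profile(participant_id: str = "perfect") -> ParticipantProfile:
    """Zero-lapse, perfect-memory agent: scores zero errors everywhere."""
    return ParticipantProfile(
        participant_id=participant_id,
        severity=0.0,
        age=30,
        gender="female",
        d2_pace=42.0,
        d2_p_omission=0.0,
        d2_p_commission=0.0,
        dmts_memory_logit=50.0,  # fidelity ~ 1 at every delay
        dmts_delay_decay=0.0,
        dmts_error_weights=(0.23, 0.58, 0.19),
        dmts_latency_log_mean=8.0,
        dmts_latency_log_sd=0.3,
        swm_p_between=0.0,
        swm_p_within=0.0,
        swm_discipline=1.0,
    )


# ---------------------------------------------------------------------------
# PHQ-9 and auxiliary scale generation
# ---------------------------------------------------------------------------


def simulate_phq9(
    profile: ParticipantProfile, rng: np.random.Generator, config: SimConfig | None = None
) -> Phq9Response:
    """Draw the 9 items from a graded-response model: the probability
    of reaching each response category rises with severity, so the
    expected total is strictly increasing in severity."""
    config = config or SimConfig()
    a = config.phq9_discrimination
    items = []
    for _ in range(9):
        shift = config.phq9_item_scatter * rng.normal()
        u = rng.random()
        score = 0
        for tau in config.phq9_thresholds:
            if u < _sigmoid(a * profile.severity - tau - shift):
                score += 1
        items.append(score)
    return Phq9Response(items=items, difficulty_item=int(rng.integers(0, 4)))


def _simulate_aux_scale(
    scale_id: str,
    n_items: int,
    max_resp: int,
    profile: ParticipantProfile,
    rng: np.random.Generator,
    config: SimConfig,
) -> ScaleResponse:
    # auxiliary scales correlate with severity (shared latent, own noise)
    latent = 0.6 * profile.severity + 0.8 * rng.normal()
    items = []
    for _ in range(n_items):
        u = rng.random()
        score = 0
        for c in range(max_resp):
            if u < _sigmoid(1.5 * latent - (0.5 + 1.2 * c)):
                score += 1
        items.append(score)
    time_s = float(n_items * rng.lognormal(np.log(config.phq9_seconds_per_item), 0.25))
    return ScaleResponse(scale_id=scale_id, item_responses=items, completion_time_s=time_s)


def simulate_scales(
    profile: ParticipantProfile, rng: np.random.Generator, config: SimConfig
) -> list[ScaleResponse]:
    """All self-report scales for one participant (honest or careless)."""
    if profile.careless is not None:
        return _careless_scales(profile.careless, rng, config)
    phq = simulate_phq9(profile, rng, config)
    phq_time = float(9 * rng.lognormal(np.log(config.phq9_seconds_per_item), 0.25))
    scales = [
        ScaleResponse(scale_id="phq9", item_responses=phq.items, completion_time_s=phq_time)
    ]
    for sid, (n_items, max_resp) in AUX_SCALES.items():
        scales.append(_simulate_aux_scale(sid, n_items, max_resp, profile, rng, config))
    return scales


def _careless_scales(
    style: CarelessStyle, rng: np.random.Generator, config: SimConfig
) -> list[ScaleResponse]:
    """Scales violating one filter on every scale (>= 3 scales total)."""
    out = []
    all_scales = [("phq9", 9, 3)] + [(s, n, m) for s, (n, m) in AUX_SCALES.items()]
    for sid, n_items, max_resp in all_scales:
        if style == "speeder":
            items = [int(rng.integers(0, max_resp + 1)) for _ in range(n_items)]
            time_s = 0.4 * n_items  # far under 1 s/item
        elif style == "straightliner":
            v = int(rng.integers(0, max_resp + 1))
            items = [v] * n_items
            time_s = float(n_items * rng.lognormal(np.log(2.0), 0.2))
        else:
            # random_clicker: maximal-variance alternation of extremes,
            # clicked through quickly.  On a bounded scale the alternation
            # variance is capped, so several clickers in one cohort can
            # inflate the outlier-variance threshold past themselves; the
            # sub-second pace makes the violation unconditional, matching
            # how insufficient-effort responders actually behave.
            start = int(rng.integers(2))
            items = [max_resp if (i + start) % 2 else 0 for i in range(n_items)]
            time_s = 0.6 * n_items
        out.append(ScaleResponse(scale_id=sid, item_responses=items, completion_time_s=time_s))
    return out


# ---------------------------------------------------------------------------
# Task-playing agents
# ---------------------------------------------------------------------------


def _play_d2(
    profile: ParticipantProfile,
    battery: Sequence[D2PageSpec],
    rng: np.random.Generator,
) -> EventLog:
    events: list[Event] = []
    t = 0
    page_ms = 15_000
    for page in battery:
        events.append(Event(t=t, kind="page_start", data={"page": page.page_index}))
        m = int(np.clip(round(profile.d2_pace + rng.normal(0, 1.0)), 1, len(page.items)))
        dt = page_ms // (m + 1)
        for idx in range(m):
            if idx > 0:
                t += dt
                events.append(Event(t=t, kind="nav_right"))
            item = page.items[idx]
            mark = (
                rng.random() > profile.d2_p_omission
                if item.is_target
                else rng.random() < profile.d2_p_commission
            )
            if mark:
                events.append(Event(t=t, kind="mark"))
        t += dt
        events.append(Event(t=t, kind="page_end"))
        t += 3_000  # inter-page break
    return EventLog(
        participant_id=profile.participant_id, task_id="d2", seed=0, events=events
    )


def _play_dmts(
    profile: ParticipantProfile,
    battery: Sequence[DMTSTrialSpec],
    rng: np.random.Generator,
) -> EventLog:
    events: list[Event] = []
    t = 0
    for trial in battery:
        events.append(Event(t=t, kind="trial_start", data={"trial": trial.trial_index}))
        t += trial.prompt_duration_ms + trial.delay_ms
        events.append(Event(t=t, kind="choices_on"))
        fidelity = profile.memory_fidelity(trial.delay_ms)
        if rng.random() < fidelity:
            first_role = "match"
        else:
            w = np.asarray(profile.dmts_error_weights, dtype=float)
            first_role = ["color_distractor", "shape_distractor", "novel_distractor"][
                int(rng.choice(3, p=w / w.sum()))
            ]
        latency = int(rng.lognormal(profile.dmts_latency_log_mean, profile.dmts_latency_log_sd))
        t += max(latency, 1)
        chosen = trial.roles.index(first_role)
        events.append(Event(t=t, kind="select", data={"choice_index": chosen}))
        # forced continuation until the match is selected
        remaining = [i for i in range(4) if i != chosen]
        while trial.roles[chosen] != "match":
            chosen = int(rng.choice(remaining))
            remaining.remove(chosen)
            t += int(rng.lognormal(7.0, 0.3))  # quicker follow-up clicks
            events.append(Event(t=t, kind="select", data={"choice_index": chosen}))
        t += 1_000
    return EventLog(
        participant_id=profile.participant_id, task_id="dmts", seed=0, events=events
    )


def _play_swm(
    profile: ParticipantProfile,
    battery: Sequence[SWMTrialSpec],
    rng: np.random.Generator,
) -> EventLog:
    events: list[Event] = []
    t = 0
    for trial in battery:
        events.append(Event(t=t, kind="trial_start", data={"trial": trial.trial_index}))
        emptied: set[int] = set()
        used_starts: set[int] = set()
        for seq in range(trial.n_boxes):
            t += 500
            events.append(Event(t=t, kind="sequence_start", data={"sequence": seq}))
            token = trial.token_schedule[seq]
            opened: set[int] = set()
            while True:
                candidates = [
                    b for b in range(trial.n_boxes) if b not in emptied and b not in opened
                ]
                # memory failures: revisit an emptied box not yet tried
                # this sequence (between error) or a box already opened
                # this sequence (within error)
                box: int | None = None
                if not opened:
                    # the first open of a sequence is a deliberate
                    # strategic choice; memory failures occur mid-search
                    if rng.random() < profile.swm_discipline:
                        box = candidates[0]  # systematic start: lowest box id
                    elif rng.random() < profile.swm_novelty:
                        # novelty-seeking start: any box not yet used as a
                        # start, even an emptied one (a between error)
                        fresh = [b for b in range(trial.n_boxes) if b not in used_starts]
                        box = int(rng.choice(fresh)) if fresh else int(rng.choice(candidates))
                    else:
                        box = int(rng.choice(candidates))
                    used_starts.add(box)
                else:
                    emptied_pool = sorted(emptied - opened)
                    revisit_pool = sorted(opened)
                    r = rng.random()
                    if r < profile.swm_p_between:
                        if emptied_pool:
                            box = int(rng.choice(emptied_pool))
                    elif r < profile.swm_p_between + profile.swm_p_within:
                        if revisit_pool:
                            box = int(rng.choice(revisit_pool))
                    if box is None:
                        box = int(rng.choice(candidates))
                t += 800
                events.append(Event(t=t, kind="open", data={"box_id": box}))
                opened.add(box)
                if box == token:
                    t += 300
                    events.append(Event(t=t, kind="token_found"))
                    emptied.add(box)
                    break
        t += 2_000
    return EventLog(
        participant_id=profile.participant_id, task_id="swm", seed=0, events=events
    )


def run_agents(
    profile: ParticipantProfile,
    batteries: Mapping[str, Sequence],
    rng: np.random.Generator,
    battery_seed: int = 0,
) -> dict[str, EventLog]:
    """Play every battery in ``batteries`` (keys among d2/dmts/swm) and
    return the resulting event logs, tagged with ``battery_seed``."""
    players = {"d2": _play_d2, "dmts": _play_dmts, "swm": _play_swm}
    logs: dict[str, EventLog] = {}
    for task_id, battery in batteries.items():
        log = players[task_id](profile, battery, rng)
        log = log.model_copy(update={"seed": battery_seed})
        logs[task_id] = log
    return logs


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Simulated participants, their profiles, and the ground truth."""

    records: list[ParticipantRecord]
    profiles: list[ParticipantProfile]
    truth: pd.DataFrame


def simulate_cohort(config: SimConfig, seed: int) -> Cohort:
    """Simulate a full cohort: profiles, scales, and task event logs.

    Reproducible: identical ``(config, seed)`` yields an identical
    cohort.  A ``careless_fraction`` > 0 plants careless responders
    (equal mix of styles) whose scale behavior violates the quality
    filters on every scale."""
    root = np.random.default_rng(seed)
    records: list[ParticipantRecord] = []
    profiles: list[ParticipantProfile] = []
    truth_rows = []

    n_careless = int(round(config.careless_fraction * config.n))
    careless_idx = set(root.choice(config.n, size=n_careless, replace=False)) if n_careless else set()
    styles: list[CarelessStyle] = ["speeder", "straightliner", "random_clicker"]

    for i in range(config.n):
        rng = np.random.default_rng(root.integers(2**31))
        pid = f"p{i + 1:04d}"
        severity = float(rng.normal(config.severity_mean, config.severity_sd))
        profile = make_profile(pid, severity, config, rng)
        if i in careless_idx:
            profile = profile.model_copy(update={"careless": styles[i % 3]})
        scales = simulate_scales(profile, rng, config)

        battery_seed = int(rng.integers(2**31))
        batteries = {
            "d2": generate_d2_battery(battery_seed, config.d2),
            "dmts": generate_dmts_battery(battery_seed, config=config.dmts),
            "swm": generate_swm_battery(battery_seed, config.swm),
        }
        logs = run_agents(profile, batteries, rng, battery_seed=battery_seed)

        records.append(
            ParticipantRecord(
                participant_id=pid,
                age=profile.age,
                gender=profile.gender,
                scales=scales,
                logs=logs,
            )
        )
        profiles.append(profile)
        truth_rows.append(
            {
                "participant_id": pid,
                "severity": severity,
                "age": profile.age,
                "gender": profile.gender,
                "careless": profile.careless or "",
                "d2_p_omission": profile.d2_p_omission,
                "d2_p_commission": profile.d2_p_commission,
                "dmts_memory_logit": profile.dmts_memory_logit,
                "swm_p_between": profile.swm_p_between,
                "swm_p_within": profile.swm_p_within,
                "battery_seed": battery_seed,
            }
        )

    return Cohort(records=records, profiles=profiles, truth=pd.DataFrame(truth_rows))


def simulate_from_fitted_model(
    coefficients: Mapping[str, float],
    predictor_moments: Mapping[str, tuple[float, float]],
    residual_sd: float,
    n: int,
    rng: np.random.Generator,
    p_male: float = reference.STUDY2_MALE_PROPORTION,
) -> pd.DataFrame:
    """Generative twin of a fitted linear model.

    Continuous predictors are drawn independently normal with the given
    (mean, sd); a ``gender`` coefficient, if present, gets a Bernoulli
    male indicator with probability ``p_male``.  The outcome is the
    linear combination plus Gaussian noise.  Used for coefficient-
    recovery checks.
    """
    if residual_sd < 0:
        raise ValueError("residual_sd must be non-negative")
    data: dict[str, np.ndarray] = {}
    for name, coef in coefficients.items():
        if name == "intercept":
            continue
        if name == "gender":
            data[name] = (rng.random(n) < p_male).astype(float)
        else:
            mean, sd = predictor_moments[name]
            data[name] = rng.normal(mean, sd, size=n)
    y = np.full(n, float(coefficients.get("intercept", 0.0)))
    for name, col in data.items():
        y = y + coefficients[name] * col
    y = y + rng.normal(0.0, residual_sd, size=n)
    data["phq9_total"] = y
    return pd.DataFrame(data)
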