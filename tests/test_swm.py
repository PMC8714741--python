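"""SWM battery generation, token placement, and scoring."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from taskphenotype.swm import (
    BOX_LEVELS,
    SWMConfig,
    SWMTrialSpec,
    SWMTrialState,
    generate_swm_battery,
    place_token,
    score_swm,
)
from taskphenotype.types import Event, EventLog


def _trial(schedule, n_boxes=None):
    n = n_boxes or len(schedule)
    return SWMTrialSpec(
        trial_index=0,
        n_boxes=n,
        box_positions=[(0.1 * i, 0.1 * i) for i in range(n)],
        token_schedule=schedule,
    )


def _events(sequences, trial=0, t0=0):
    """Build one trial's events: each inner list is the boxes opened in
    one sequence, which ends with token_found at its last open."""
    events = [Event(t=t0, kind="trial_start", data={"trial": trial})]
    t = t0
    for s, opens in enumerate(sequences):
        t += 10
        events.append(Event(t=t, kind="sequence_start", data={"sequence": s}))
        for box in opens:
            t += 10
            events.append(Event(t=t, kind="open", data={"box_id": box}))
        t += 10
        events.append(Event(t=t, kind="token_found"))
    return events, t


def _log(events):
    return EventLog(participant_id="p", task_id="swm", seed=0, events=events)


class TestGeneration:
    def test_six_trials_ascending_levels(self):
        battery = generate_swm_battery(seed=2)
        assert [t.n_boxes for t in battery] == list(BOX_LEVELS)
        assert [t.trial_index for t in battery] == list(range(6))

    def test_same_seed_identical(self):
        assert generate_swm_battery(3) == generate_swm_battery(3)
        assert generate_swm_battery(3) != generate_swm_battery(4)

    @given(seed=st.integers(0, 2**20))
    @settings(max_examples=25, deadline=None)
    def test_schedule_is_always_a_permutation(self, seed):
        for trial in generate_swm_battery(seed):
            assert sorted(trial.token_schedule) == list(range(trial.n_boxes))

    def test_non_permutation_schedule_rejected(self):
        with pytest.raises(ValueError, match="permutation"):
            _trial([0, 0, 1, 2])


class TestPlaceToken:
    def test_only_non_emptied_boxes_eligible(self, rng):
        state = SWMTrialState(n_boxes=4, emptied={0, 2})
        draws = {place_token(state, rng) for _ in range(100)}
        assert draws == {1, 3}

    def test_all_emptied_raises(self, rng):
        with pytest.raises(ValueError, match="non-emptied"):
            place_token(SWMTrialState(n_boxes=2, emptied={0, 1}), rng)

    def test_placement_is_uniform(self, rng):
        state = SWMTrialState(n_boxes=8)
        counts = Counter(place_token(state, rng) for _ in range(8000))
        observed = [counts[b] for b in range(8)]
        assert stats.chisquare(observed).pvalue > 1e-3


class TestScoringHandTraces:
    def test_strategy_counts_distinct_sequence_starts(self):
        # starts at boxes 0, 0, 2, 3 -> three distinct starts
        battery = [_trial([1, 0, 2, 3])]
        events, _ = _events([[0, 1], [0], [2], [3]])
        m = score_swm(_log(events), battery)
        assert m.strategy_score == 3
        assert m.n_between_errors == 0 and m.n_within_errors == 0

    def test_double_open_of_emptied_box(self):
        # sequence 1 opens box 1 (emptied in sequence 0) twice:
        # first open -> between; second -> within, and between again
        # under the default double-count rule
        battery = [_trial([1, 0, 2, 3])]
        events, _ = _events([[1], [1, 1, 0], [2], [3]])
        m = score_swm(_log(events), battery)
        assert m.n_between_errors == 2
        assert m.n_within_errors == 1
        m2 = score_swm(_log(events), battery, SWMConfig(double_count_overlap=False))
        assert m2.n_between_errors == 1
        assert m2.n_within_errors == 1

    def test_within_error_on_plain_revisit(self):
        # revisiting a non-emptied box in the same sequence is within-only
        battery = [_trial([1, 0, 2, 3])]
        events, _ = _events([[0, 0, 1], [0], [2], [3]])
        m = score_swm(_log(events), battery)
        assert (m.n_between_errors, m.n_within_errors) == (0, 1)

    def test_metrics_sum_across_trials(self):
        battery = [_trial([1, 0]), _trial([0, 1])]
        ev0, t = _events([[0, 1], [0]], trial=0)
        battery[1] = battery[1].model_copy(update={"trial_index": 1})
        ev1, _ = _events([[0], [1]], trial=1, t0=t + 10)
        m = score_swm(_log(ev0 + ev1), battery)
        # trial 0 starts both sequences at box 0; trial 1 uses two starts
        assert m.strategy_score == 1 + 2


class TestScoringErrors:
    def test_unknown_box_rejected(self):
        events = [
            Event(t=0, kind="trial_start", data={"trial": 0}),
            Event(t=1, kind="sequence_start", data={"sequence": 0}),
            Event(t=2, kind="open", data={"box_id": 99}),
        ]
        with pytest.raises(ValueError, match="unknown box"):
            score_swm(_log(events), [_trial([1, 0])])

    def test_token_found_at_wrong_box_rejected(self):
        events = [
            Event(t=0, kind="trial_start", data={"trial": 0}),
            Event(t=1, kind="sequence_start", data={"sequence": 0}),
            Event(t=2, kind="open", data={"box_id": 0}),
            Event(t=3, kind="token_found"),
        ]
        with pytest.raises(ValueError, match="hides it in box 1"):
            score_swm(_log(events), [_trial([1, 0])])

    def test_open_outside_sequence_rejected(self):
        events = [
            Event(t=0, kind="trial_start", data={"trial": 0}),
            Event(t=1, kind="open", data={"box_id": 0}),
        ]
        with pytest.raises(ValueError, match="outside a sequence"):
            score_swm(_log(events), [_trial([1, 0])])


def _replay_oracle(log, battery, double_count=True):
    """Independent straight-line recomputation of the three measures."""
    between = within = strategy = 0
    trial = None
    for ev in log.events:
        if ev.kind == "trial_start":
            if trial is not None:
                strategy += len(starts)
            trial = ev.data["trial"]
            emptied, starts = [], []
        elif ev.kind == "sequence_start":
            seq = ev.data["sequence"]
            opened = []
        elif ev.kind == "open":
            box = ev.data["box_id"]
            w = box in opened
            b = box in emptied
            within += int(w)
            between += int(b and (double_count or not w))
            if not opened:
                starts.append(box) if box not in starts else None
            opened.append(box)
        elif ev.kind == "token_found":
            emptied.append(battery[trial].token_schedule[seq])
    if trial is not None:
        strategy += len(starts)
    return between, within, strategy


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 2**20), agent_seed=st.integers(0, 2**20))
def test_scoring_matches_independent_replay(seed, agent_seed):
    from taskphenotype.simulate import perfect_profile, _play_swm

    battery = generate_swm_battery(seed)
    rng = np.random.default_rng(agent_seed)
    profile = perfect_profile().model_copy(
        update={
            "swm_p_between": float(rng.uniform(0, 0.4)),
            "swm_p_within": float(rng.uniform(0, 0.4)),
            "swm_discipline": float(rng.uniform(0, 1)),
            "swm_novelty": float(rng.uniform(0, 1)),
        }
    )
    log = _play_swm(profile, battery, rng)
    m = score_swm(log, battery)
    assert (m.n_between_errors, m.n_within_errors, m.strategy_score) == _replay_oracle(
        log, battery
    )


@settings(max_examples=10, deadline=None)
@given(seed=st.integers(0, 2**20))
def test_perfect_agent_never_errs(seed):
    from taskphenotype.simulate import perfect_profile, _play_swm

    battery = generate_swm_battery(seed)
    rng = np.random.default_rng(seed + 1)
    m = score_swm(_play_swm(perfect_profile(), battery, rng), battery)
    assert m.n_between_errors == 0 and m.n_within_errors == 0
    # six trials, each with at least one sequence start
    assert 6 <= m.strategy_score <= sum(BOX_LEVELS)
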