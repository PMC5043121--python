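import numpy as np
import pandas as pd
import pytest

import dodgekin as dk
from dodgekin.game import sample_schedule_intervals


@pytest.fixture(scope="module")
def full_schedule(ih_sets):
    return dk.generate_schedule(dk.ScheduleConfig(seed=1), ih_sets)


def test_event_counts(full_schedule):
    launched = full_schedule.launched
    game = [e for e in launched if e.level >= 1]
    assert len(game) == 90                       # 2 sets x 15 x 3 levels
    assert len([e for e in launched if e.level == 0]) == 30  # practice
    assert len(full_schedule.bonus) == 6         # one per game-level set
    for level in (1, 2, 3):
        for s in (0, 1):
            in_set = [e for e in game if e.level == level and e.set_index == s]
            assert len(in_set) == 15
            for ih in range(5):
                hits = [e for e in in_set if e.impact_height_index == ih]
                assert len(hits) == 3
                assert sorted(e.lateral_offset for e in hits) == \
                    [-0.20, 0.0, 0.20]


def test_warning_lead_and_duck_rule(full_schedule):
    for e in full_schedule.launched:
        assert e.launch_time - e.warning_time == pytest.approx(0.300)
        assert (e.trial_type == "duck") == (e.impact_height_index == 0)
        assert 1 <= e.opponent_id <= 4


def test_interval_sample_mean(ih_sets):
    iv = sample_schedule_intervals(dk.ScheduleConfig(), ih_sets, 10_000, seed=1)
    assert iv.size == 10_000
    assert np.all((iv >= 3.0) & (iv <= 3.6))
    assert 3.28 <= iv.mean() <= 3.32


def test_schedule_determinism(ih_sets):
    a = dk.generate_schedule(dk.ScheduleConfig(seed=7), ih_sets)
    b = dk.generate_schedule(dk.ScheduleConfig(seed=7), ih_sets)
    c = dk.generate_schedule(dk.ScheduleConfig(seed=8), ih_sets)
    fa, fb, fc = (dk.schedule_to_frame(s) for s in (a, b, c))
    pd.testing.assert_frame_equal(fa, fb)
    assert not fa.equals(fc)


def test_config_invariants():
    with pytest.raises(ValueError):
        dk.ScheduleConfig(balls_per_set=14)
    with pytest.raises(ValueError):
        dk.ScheduleConfig(lateral_offsets=(-0.2, 0.0, 0.1),
                          balls_per_height=3)


def test_initial_balance_enumeration(full_schedule):
    scoring = dk.ScoringConfig()
    # 30 balls at each of 1/2/5/10 cents plus six 25-cent bonus balls
    assert dk.initial_balance(full_schedule, scoring) == \
        30 * 1 + 30 * 2 + 30 * 5 + 30 * 10 + 6 * 25 == 690


def test_empty_schedule_balance(ih_sets):
    empty = dk.GameSchedule([], dk.ScheduleConfig(), ih_sets)
    assert dk.initial_balance(empty, dk.ScoringConfig()) == 0


def test_all_failure_session_ends_at_zero(full_schedule):
    scoring = dk.ScoringConfig()
    ledger = dk.ScoreLedger(dk.initial_balance(full_schedule, scoring))
    for e in full_schedule.events:
        dk.apply_score(ledger, e, False, scoring)
    assert ledger.final_balance_cents == 0
    assert ledger.final_balance_cents == \
        ledger.initial_balance_cents + sum(d for _, d, _ in ledger.entries)


def test_reward_values(full_schedule):
    scoring = dk.ScoringConfig()
    lvl3 = next(e for e in full_schedule.launched if e.level == 3)
    bonus = full_schedule.bonus[0]
    ledger = dk.ScoreLedger(0)
    dk.apply_score(ledger, lvl3, True, scoring)
    dk.apply_score(ledger, bonus, True, scoring)
    assert [d for _, d, _ in ledger.entries] == [10, 25]
    assert scoring.reward_cents == {0: 1, 1: 2, 2: 5, 3: 10}


def test_rewards_must_increase():
    with pytest.raises(ValueError):
        dk.ScoringConfig(reward_cents={0: 5, 1: 2, 2: 5, 3: 10})


def _block_event(t=10.0):
    return dk.LaunchEvent(event_id=0, level=1, set_index=0, launch_time=t,
                          warning_time=t - 0.3, opponent_id=1,
                          trial_type="block", impact_height_index=2,
                          lateral_offset=0.0, flight_time=0.8)


def _duck_event(t=10.0):
    return dk.LaunchEvent(event_id=1, level=1, set_index=0, launch_time=t,
                          warning_time=t - 0.3, opponent_id=2,
                          trial_type="duck", impact_height_index=0,
                          lateral_offset=0.0, flight_time=0.8)


def test_judge_block_hit_and_miss():
    e = _block_event()
    impact = np.array([0.45, 0.0, 1.2])
    path = dk.ball_path(impact, 0.0, e.flight_time, np.array([8.0, 0, 1.5]))
    times = np.arange(9.0, 12.0, 0.01)
    hand_hit = np.tile(impact, (times.size, 1))
    hand_miss = hand_hit + np.array([0.0, 1.0, 0.0])
    head = np.full(times.size, 1.7)
    assert dk.judge_trial(e, times, hand_hit, head, path) is True
    assert dk.judge_trial(e, times, hand_miss, head, path) is False


def test_judge_duck_by_head_clearance():
    e = _duck_event()
    impact = np.array([0.45, 0.0, 1.6])
    path = dk.ball_path(impact, 0.0, e.flight_time, np.array([8.0, 0, 1.6]))
    times = np.arange(9.0, 12.0, 0.01)
    hand = np.zeros((times.size, 3))
    lowered = np.full(times.size, 1.72 - 0.4)
    upright = np.full(times.size, 1.72)
    assert dk.judge_trial(e, times, hand, lowered, path) is True
    assert dk.judge_trial(e, times, hand, upright, path) is False


def test_judge_unjudgeable_without_coverage():
    e = _block_event(t=10.0)
    path = dk.ball_path(np.array([0.45, 0, 1.2]), 0.0, 0.8,
                        np.array([8.0, 0, 1.5]))
    times = np.arange(0.0, 5.0, 0.01)  # ends before the flight window
    assert dk.judge_trial(e, times, np.zeros((times.size, 3)),
                          np.zeros(times.size), path) is None


def test_duck_event_invariant():
    with pytest.raises(ValueError):
        dk.LaunchEvent(event_id=0, level=1, set_index=0, launch_time=1.0,
                       warning_time=0.7, opponent_id=1, trial_type="duck",
                       impact_height_index=3, lateral_offset=0.0,
                       flight_time=0.8)


def test_success_rate():
    ledger = dk.ScoreLedger(0)
    scoring = dk.ScoringConfig()
    e = _block_event()
    for i in range(90):
        dk.apply_score(ledger, e, i < 45, scoring)
    assert dk.success_rate(ledger) == pytest.approx(50.0)
    with pytest.raises(ValueError):
        dk.success_rate(dk.ScoreLedger(0))


def test_strategy_profiles_change_success_rate(ih_sets, dims):
    """A profile tuned to intercept far forward and low misses laterally
    offset balls a neutral profile blocks, so judged success rates differ in
    the programmed direction."""
    schedule = dk.generate_schedule(
        dk.ScheduleConfig(levels=1, practice=False, seed=5), ih_sets)
    scoring = dk.ScoringConfig()
    rates = {}
    for name, prof in [("neutral", dk.StrategyProfile()),
                       ("biased", dk.StrategyProfile(forward_bias=0.30,
                                                     crouch_bias=0.15))]:
        sess = dk.simulate_session(schedule, dims, prof, seed=4,
                                   noise_std=0.0)
        times, hand, head = sess.player_trace()
        ledger = dk.ScoreLedger(dk.initial_balance(schedule, scoring))
        for e in schedule.launched:
            z = schedule.impact_height(e)
            path = dk.ball_path(np.array([0.45, 0.0, z]), e.lateral_offset,
                                e.flight_time, np.array([8.0, 0.0, 1.5]))
            dk.apply_score(ledger, e,
                           dk.judge_trial(e, times, hand, head, path), scoring)
        rates[name] = dk.success_rate(ledger)
    assert rates["neutral"] == pytest.approx(100.0)
    assert rates["biased"] < rates["neutral"]
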