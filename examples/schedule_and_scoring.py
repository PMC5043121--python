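"""Launch schedule, trial judging and the cash ledger.

Generates a full round (practice + 3 levels, 2 sets of 15 balls each),
simulates a player, judges every launched ball against the ball paths and
tallies the cash rewards.
"""

import numpy as np

import dodgekin as dk

dims = dk.BodyDimensions(1.0, 0.5, 0.7, 1.6, 0.45)
baseline = dk.LumbarBaseline(15.0, 30.0, 60.0)
ih_sets = {lvl: dk.impact_heights_for_level(dims, baseline, lvl)
           for lvl in (1, 2, 3)}

schedule = dk.generate_schedule(dk.ScheduleConfig(seed=42), ih_sets)
intervals = dk.inter_launch_intervals(schedule)
print(f"launched balls: {len(schedule.launched)} "
      f"(game levels: {sum(e.level >= 1 for e in schedule.launched)}), "
      f"bonus balls: {len(schedule.bonus)}")
print(f"inter-launch intervals: mean {intervals.mean():.2f} s, "
      f"range [{intervals.min():.2f}, {intervals.max():.2f}] s")

scoring = dk.ScoringConfig()
start = dk.initial_balance(schedule, scoring)
print(f"starting balance: {start} cents (all-failure play ends at zero)")

session = dk.simulate_session(schedule, dims, dk.StrategyProfile(), seed=42)
times, hand, head = session.player_trace()
ledger = dk.ScoreLedger(start)
for e in schedule.launched:
    z = schedule.impact_height(e)
    path = dk.ball_path(np.array([0.45, 0.0, z]), e.lateral_offset,
                        e.flight_time, launch_origin=np.array([8.0, 0.0, 1.5]))
    dk.apply_score(ledger, e, dk.judge_trial(e, times, hand, head, path),
                   scoring)
print(f"success rate: {dk.success_rate(ledger):.1f}% | "
      f"final balance: {ledger.final_balance_cents} cents")

# Every successful block/duck adds the level's reward (1/2/5/10 cents) and
# every failure subtracts it, so the final balance tracks performance
# exactly as the in-game scoreboard would.
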