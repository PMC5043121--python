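"""Launch schedules, block/duck judging, and the cash-reward ledger.

A round consists of an optional practice level and three game levels, each
with two sets of 15 launched balls: three balls per impact height (IH0-IH4)
per set, one at each lateral offset (-20, 0, +20 cm from the midline).
Balls launch every 3.3 +/- 0.3 s (uniform jitter) in randomized order from
four opponents, with a 300 ms color-change warning before each launch.
Balls aimed at IH0 (eye height) must be ducked; all others blocked with the
hand-held ball.  After each game-level set a static bonus ball is presented.

Rewards scale with level (practice 1 cent, levels 1-3 = 2/5/10 cents, bonus
25 cents); each failure loses the same amount, and the starting balance is
the sum of all per-ball values so that failing every ball leaves exactly
zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ScheduleConfig",
    "LaunchEvent",
    "GameSchedule",
    "ScoringConfig",
    "ScoreLedger",
    "generate_schedule",
    "inter_launch_intervals",
    "sample_schedule_intervals",
    "initial_balance",
    "judge_trial",
    "apply_score",
    "success_rate",
    "schedule_to_frame",
]

BALL_RADIUS = 0.12  # regulation dodgeball, 24 cm diameter


@dataclass(frozen=True)
class ScheduleConfig:
    """Parameters of one round of play."""

    opponents: int = 4
    interval_mean: float = 3.3
    interval_halfwidth: float = 0.3
    warning_lead: float = 0.300
    sets_per_level: int = 2
    balls_per_set: int = 15
    balls_per_height: int = 3
    lateral_offsets: tuple = (-0.20, 0.0, 0.20)
    levels: int = 3
    practice: bool = True
    set_break: float = 8.0
    start_time: float = 5.0
    flight_time: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.balls_per_set != self.balls_per_height * 5:
            raise ValueError("balls_per_set must equal 5 * balls_per_height")
        offs = sorted(self.lateral_offsets)
        if any(abs(a + b) > 1e-12 for a, b in zip(offs, reversed(offs))):
            raise ValueError("lateral offsets must be symmetric about 0")
        if len(self.lateral_offsets) != self.balls_per_height:
            raise ValueError("need one lateral offset per ball at each height")
        if self.interval_mean - self.interval_halfwidth <= 0:
            raise ValueError("interval jitter exceeds the mean interval")
        if self.warning_lead <= 0 or self.flight_time <= 0:
            raise ValueError("warning_lead and flight_time must be positive")


@dataclass(frozen=True)
class LaunchEvent:
    """One launched (or bonus) ball."""

    event_id: int
    level: int                  # 0 = practice
    set_index: int
    launch_time: float
    warning_time: float
    opponent_id: int
    trial_type: str             # block | duck | bonus
    impact_height_index: int | None
    lateral_offset: float
    flight_time: float

    def __post_init__(self) -> None:
        if self.trial_type not in ("block", "duck", "bonus"):
            raise ValueError(f"unknown trial_type {self.trial_type!r}")
        if self.trial_type != "bonus":
            if not self.warning_time < self.launch_time:
                raise ValueError("warning must precede launch")
            if (self.trial_type == "duck") != (self.impact_height_index == 0):
                raise ValueError("duck trials occur exactly at IH0")

    @property
    def impact_time(self) -> float:
        return self.launch_time + self.flight_time


@dataclass
class GameSchedule:
    """Ordered launch events plus per-level impact-height sets."""

    events: list
    config: ScheduleConfig
    ih_sets: dict  # level -> ImpactHeightSet

    @property
    def launched(self) -> list:
        return [e for e in self.events if e.trial_type != "bonus"]

    @property
    def bonus(self) -> list:
        return [e for e in self.events if e.trial_type == "bonus"]

    def impact_height(self, event: LaunchEvent) -> float:
        """Vertical impact coordinate of a launched event, meters."""
        if event.trial_type == "bonus":
            raise ValueError("bonus balls are static, not launched")
        level = event.level if event.level >= 1 else 1
        return self.ih_sets[level][event.impact_height_index]


def generate_schedule(cfg: ScheduleConfig, ih_sets: dict) -> GameSchedule:
    """Generate a full round of launch events.

    ``ih_sets`` maps level (1..levels) to its ImpactHeightSet; practice play
    reuses the Level-1 heights.  Deterministic under ``cfg.seed``: the same
    seed reproduces the schedule bit for bit.
    """
    for level in range(1, cfg.levels + 1):
        if level not in ih_sets:
            raise ValueError(f"missing impact-height set for level {level}")
    rng = np.random.default_rng(cfg.seed)
    events = []
    t = cfg.start_time
    eid = 0
    levels = ([0] if cfg.practice else []) + list(range(1, cfg.levels + 1))
    for level in levels:
        for set_index in range(cfg.sets_per_level):
            menu = [(ih, off) for ih in range(5) for off in cfg.lateral_offsets]
            order = rng.permutation(len(menu))
            first_in_set = True
            for j in order:
                ih, off = menu[j]
                if not first_in_set:
                    t += rng.uniform(cfg.interval_mean - cfg.interval_halfwidth,
                                     cfg.interval_mean + cfg.interval_halfwidth)
                first_in_set = False
                events.append(LaunchEvent(
                    event_id=eid, level=level, set_index=set_index,
                    launch_time=t, warning_time=t - cfg.warning_lead,
                    opponent_id=int(rng.integers(1, cfg.opponents + 1)),
                    trial_type="duck" if ih == 0 else "block",
                    impact_height_index=ih, lateral_offset=off,
                    flight_time=cfg.flight_time))
                eid += 1
            t += cfg.set_break
            if level >= 1:  # static bonus ball after each game-level set
                events.append(LaunchEvent(
                    event_id=eid, level=level, set_index=set_index,
                    launch_time=t, warning_time=t, opponent_id=0,
                    trial_type="bonus", impact_height_index=None,
                    lateral_offset=0.0, flight_time=cfg.flight_time))
                eid += 1
                t += cfg.set_break
    return GameSchedule(events=events, config=cfg, ih_sets=dict(ih_sets))


def sample_schedule_intervals(cfg: ScheduleConfig, ih_sets: dict, n: int,
                              seed: int = 0) -> np.ndarray:
    """Collect at least ``n`` inter-launch intervals by generating schedules
    with seeds spawned from ``seed``."""
    out = []
    total = 0
    k = 0
    rng = np.random.default_rng(seed)
    while total < n:
        sub = int(rng.integers(0, 2**31 - 1))
        sch = generate_schedule(replace(cfg, seed=sub), ih_sets)
        iv = inter_launch_intervals(sch)
        out.append(iv)
        total += iv.size
        k += 1
    return np.concatenate(out)[:n]


def inter_launch_intervals(schedule: GameSchedule) -> np.ndarray:
    """Within-set intervals between consecutive launches, seconds."""
    out = []
    by_set = {}
    for e in schedule.launched:
        by_set.setdefault((e.level, e.set_index), []).append(e.launch_time)
    for times in by_set.values():
        out.append(np.diff(np.sort(times)))
    return np.concatenate(out) if out else np.array([])


@dataclass(frozen=True)
class ScoringConfig:
    """Cash values (cents) per level, bonus value, and the loss rule."""

    reward_cents: dict = field(default_factory=lambda: {0: 1, 1: 2, 2: 5, 3: 10})
    bonus_cents: int = 25
    loss_equals_reward: bool = True

    def __post_init__(self) -> None:
        levels = sorted(self.reward_cents)
        vals = [self.reward_cents[k] for k in levels]
        if any(a >= b for a, b in zip(vals, vals[1:])):
            raise ValueError("rewards must strictly increase across levels")

    def value(self, event: LaunchEvent) -> int:
        if event.trial_type == "bonus":
            return self.bonus_cents
        return self.reward_cents[event.level]


@dataclass
class ScoreLedger:
    """Per-trial cash deltas on top of the starting balance."""

    initial_balance_cents: int
    entries: list = field(default_factory=list)  # (event_id, delta, success)

    @property
    def final_balance_cents(self) -> int:
        return self.initial_balance_cents + sum(d for _, d, _ in self.entries)


def initial_balance(schedule: GameSchedule, scoring: ScoringConfig) -> int:
    """Starting balance: the sum of every ball's value, so an all-failure
    session ends at exactly zero."""
    if not scoring.loss_equals_reward:
        raise ValueError("the zero-balance rule requires loss_equals_reward")
    return sum(scoring.value(e) for e in schedule.events)


def judge_trial(event: LaunchEvent, times: np.ndarray, hand: np.ndarray,
                head_top: np.ndarray, ball,
                ball_radius: float = BALL_RADIUS,
                duck_margin: float = 0.05):
    """Judge one launched ball against the player's kinematics.

    Parameters
    ----------
    event:
        The launch event (block or duck).
    times, hand, head_top:
        Player sample times (s, absolute), hand-held-ball center positions
        ``(T, 3)``, and head-top heights ``(T,)``.
    ball:
        Parametric ball path (callable of time since launch), e.g.
        :class:`~dodgekin.targets.BallPath`.

    Returns
    -------
    bool or None
        Block success: the hand-held ball touches the launched ball (center
        distance <= two radii) at some instant of flight.  Duck success: the
        head top passes below the ball path's lower edge (with a safety
        margin) at crossing time.  ``None`` if the player series does not
        cover the flight window (trial unjudgeable).
    """
    times = np.asarray(times, dtype=float)
    t0, t1 = event.launch_time, event.impact_time
    if times.size == 0 or times[0] > t0 or times[-1] < t1:
        return None
    sel = (times >= t0) & (times <= t1)
    if event.trial_type == "duck":
        z_ball = ball(t1 - t0)[-1]
        h = np.interp(t1, times, np.asarray(head_top, dtype=float))
        if np.isnan(h):
            return None
        return bool(h <= z_ball - ball_radius - duck_margin)
    tt = times[sel]
    hand_w = np.asarray(hand, dtype=float)[sel]
    if np.isnan(hand_w).any():
        return None
    ball_pos = ball(tt - t0)
    dist = np.linalg.norm(hand_w - ball_pos, axis=1)
    return bool((dist <= 2.0 * ball_radius).any())


def apply_score(ledger: ScoreLedger, event: LaunchEvent, success,
                scoring: ScoringConfig) -> ScoreLedger:
    """Append one judged trial to the ledger (in place) and return it.

    Success adds the ball's value; failure subtracts it when
    ``loss_equals_reward``.  Unjudgeable trials (``success is None``) record
    a zero delta.
    """
    value = scoring.value(event)
    if success is None:
        delta = 0
    elif success:
        delta = value
    else:
        delta = -value if scoring.loss_equals_reward else 0
    ledger.entries.append((event.event_id, delta, success))
    return ledger


def success_rate(ledger: ScoreLedger) -> float:
    """Percentage of judged trials that succeeded."""
    judged = [s for _, _, s in ledger.entries if s is not None]
    if not judged:
        raise ValueError("success rate undefined with zero judged trials")
    return 100.0 * sum(judged) / len(judged)


def schedule_to_frame(schedule: GameSchedule) -> pd.DataFrame:
    """Schedule as a table, one row per event (exportable to CSV)."""
    rows = [{
        "event_id": e.event_id, "level": e.level, "set_index": e.set_index,
        "launch_time": e.launch_time, "warning_time": e.warning_time,
        "opponent_id": e.opponent_id, "trial_type": e.trial_type,
        "impact_height_index": e.impact_height_index,
        "lateral_offset": e.lateral_offset, "flight_time": e.flight_time,
    } for e in schedule.events]
    return pd.DataFrame(rows)
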