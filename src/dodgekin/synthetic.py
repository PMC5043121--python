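"""Ground-truth-labeled synthetic reaching sessions.

The generator drives the sagittal linkage of :mod:`dodgekin.bodymodel` with
minimum-jerk joint programs and emits noisy marker-cluster trajectories
together with the ground truth the reduction pipeline should recover.

A :class:`StrategyProfile` controls how a reach is composed:

* ``apportionment_weights`` split the scaled joint excursion across the six
  joints (the scale is solved so the fingertip reaches the target height);
* ``forward_bias`` adds a whole-body forward lean (extra ankle inclination)
  producing that much extra AP hand displacement at contact;
* ``crouch_bias`` adds a squat component (ankle/knee/hip pattern) producing
  that much extra downward COM displacement.

Biases apply to block trials only; duck trials use a pure squat program
that drops the head below the ball path, emulating the empirical finding
that ducking strategies do not differ between display conditions.

Ground-truth events (onset, peak, contact) are defined operationally, by
running the package's Savitzky-Golay speed estimate and 5%-of-peak
threshold rule on the *noiseless* fingertip trajectory; excursions, COM
displacement and hand position are then read off the noiseless program at
those samples.  Pipeline recovery tests therefore isolate the
marker -> pose -> signal chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .bodymodel import JOINT_ORDER, BodyModel
from .events import FilterConfig, detect_contact, detect_onset, savgol_velocity
from .io_formats import TrajectorySet
from .targets import BodyDimensions

__all__ = [
    "StrategyProfile",
    "GroundTruth",
    "SimulatedTrial",
    "SimulatedSession",
    "InfeasibleStrategyError",
    "minimum_jerk",
    "simulate_reach",
    "simulate_session",
]

#: default marker noise, meters (isotropic Gaussian per marker per frame)
DEFAULT_NOISE_STD = 0.0005

#: squat pattern (ankle, knee, hip, spine, shoulder, elbow) that lowers the
#: body while keeping the trunk near vertical and the hip over the ankle
_SQUAT = np.array([0.5, 1.0, 0.5, 0.0, 0.0, 0.0])

_DEFAULT_WEIGHTS = {"ankle": 0.05, "knee": 0.10, "hip": 0.35,
                    "spine": 0.25, "shoulder": 0.20, "elbow": 0.05}


class InfeasibleStrategyError(ValueError):
    """The weighted joint program cannot place the hand at the target."""


@dataclass(frozen=True)
class StrategyProfile:
    """Joint-excursion apportionment and strategy biases for one condition."""

    apportionment_weights: dict = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    forward_bias: float = 0.0
    crouch_bias: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.apportionment_weights) - set(JOINT_ORDER)
        if unknown:
            raise ValueError(f"unknown joints in weights: {sorted(unknown)}")
        w = np.array([self.apportionment_weights.get(j, 0.0)
                      for j in JOINT_ORDER])
        if (w < 0).any():
            raise ValueError("apportionment weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("apportionment weights must sum to 1")
        if self.forward_bias < 0 or self.crouch_bias < 0:
            raise ValueError("biases must be nonnegative")

    @property
    def weight_vector(self) -> np.ndarray:
        return np.array([self.apportionment_weights.get(j, 0.0)
                         for j in JOINT_ORDER])


@dataclass
class GroundTruth:
    """What the reduction pipeline should recover for one trial."""

    onset_index: int
    peak_index: int
    contact_index: int
    movement_time_ms: float
    excursions: dict                 # joint -> degrees
    com_displacement: np.ndarray     # (AP, ML, vertical) m
    hand_at_contact: np.ndarray      # (AP, ML, vertical) m, ankle-referenced


@dataclass
class SimulatedTrial:
    """One synthetic reach: marker data plus its ground truth."""

    trajectories: TrajectorySet
    ground_truth: GroundTruth
    contact_posture: np.ndarray      # joint angles (deg) at contact
    start_posture: np.ndarray
    duration: float
    event_id: int | None = None
    window: tuple | None = None      # (start, stop) frames in a session


@dataclass
class SimulatedSession:
    """Full synthetic game: concatenated markers and per-trial ground truth."""

    trajectories: TrajectorySet
    trials: list
    schedule: object
    model: BodyModel
    profile: StrategyProfile

    def player_trace(self):
        """(times, hand-centroid positions, head-top heights) for judging,
        from the noiseless model positions."""
        times = self.trajectories.times
        return times, self._hand_centroid, self._head_top


def minimum_jerk(duration: float, sample_rate: float):
    """Normalized minimum-jerk profile sampled at ``sample_rate``.

    Returns ``(position, speed)`` with position 10 tau^3 - 15 tau^4 +
    6 tau^5 rising 0 -> 1 over ``duration`` seconds and speed its time
    derivative (1/s), zero at both ends with a single interior peak of
    1.875 / duration at the midpoint.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * sample_rate)) + 1
    tau = np.linspace(0.0, 1.0, n)
    pos = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    speed = (30 * tau**2 - 60 * tau**3 + 30 * tau**4) / duration
    return pos, speed


# ----------------------------------------------------------- posture solving

def _fingertip(model: BodyModel, alpha: np.ndarray) -> np.ndarray:
    return model.joint_positions(alpha)["fingertip"]


def _solve_bracketed(f, lo, hi, n_grid=61):
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([f(g) for g in grid])
    if vals[0] == 0.0:
        return float(grid[0])
    sign0 = np.sign(vals[0])
    for i in range(1, n_grid):
        if vals[i] == 0.0:
            return float(grid[i])
        if np.sign(vals[i]) != sign0:
            return float(brentq(f, grid[i - 1], grid[i], xtol=1e-10))
    return None


def _contact_posture(model: BodyModel, target: np.ndarray,
                     profile: StrategyProfile) -> np.ndarray:
    """Joint angles at contact: weighted excursions scaled to the target
    height, then forward-lean and crouch biases."""
    alpha0 = model.standing_posture
    target = np.asarray(target, dtype=float)
    tip0 = _fingertip(model, alpha0)
    dz = target[-1] - tip0[-1]
    w = profile.weight_vector
    if dz > 0:
        # upward reach: postural flexion cannot raise the hand, so the
        # arm weights (shoulder, elbow) carry it
        w = w * np.array([0, 0, 0, 0, 1, 1], dtype=float)
        if w.sum() == 0:
            w = np.array([0, 0, 0, 0, 1.0, 0])
        w = w / w.sum()
    f = lambda s: float(_fingertip(model, alpha0 + s * w)[-1]) - target[-1]
    s = _solve_bracketed(f, 0.0, 240.0)
    if s is None:
        raise InfeasibleStrategyError(
            f"cannot reach target height {target[-1]:.3f} m with the given "
            "apportionment weights")
    alpha = alpha0 + s * w

    if profile.forward_bias > 0:
        e_ankle = np.eye(6)[0]
        ap0 = float(_fingertip(model, alpha)[0])
        g = lambda d: float(_fingertip(model, alpha + d * e_ankle)[0]) \
            - ap0 - profile.forward_bias
        d = _solve_bracketed(g, 0.0, 60.0)
        if d is None:
            raise InfeasibleStrategyError("forward_bias out of reach")
        alpha = alpha + d * e_ankle

    if profile.crouch_bias > 0:
        com_z = lambda a: float(model.com_trajectory(a).position[0, 2])
        z0 = com_z(alpha)
        h = lambda k: com_z(alpha + k * _SQUAT) - (z0 - profile.crouch_bias)
        k = _solve_bracketed(h, 0.0, 90.0)
        if k is None:
            raise InfeasibleStrategyError("crouch_bias out of reach")
        alpha = alpha + k * _SQUAT
    return alpha


def _duck_posture(model: BodyModel, clearance_height: float) -> np.ndarray:
    """Squat program dropping the head top to ``clearance_height``."""
    alpha0 = model.standing_posture
    head_z = lambda a: float(model.joint_positions(a)["head_top"][-1])
    f = lambda k: head_z(alpha0 + k * _SQUAT) - clearance_height
    k = _solve_bracketed(f, 0.0, 110.0)
    if k is None:
        raise InfeasibleStrategyError("cannot duck below the ball path")
    return alpha0 + k * _SQUAT


# ----------------------------------------------------------- trial synthesis

def _hand_centroid_and_head(model: BodyModel, alpha_t: np.ndarray):
    """Noiseless hand centroid (both hands) and head-top height series."""
    pos = model.joint_positions(alpha_t)
    poses = model.segment_poses(alpha_t)
    R, origin = poses["hand"]
    hand_r = np.einsum("fij,kj->fki", R,
                       model.cluster_by_segment["hand"].template_points) \
        + origin[:, None, :]
    centroid_r = hand_r.mean(axis=1)
    centroid = centroid_r * np.array([1.0, 0.0, 1.0])  # average with mirror
    return centroid, pos["head_top"][:, 2], pos["ankle"]


def _ground_truth(model: BodyModel, alpha_t: np.ndarray, sample_rate: float,
                  window: tuple, cfg: FilterConfig | None = None) -> GroundTruth:
    """Operational ground truth from the noiseless program on ``window``."""
    cfg = cfg or FilterConfig(sample_interval=1.0 / sample_rate)
    w0, w1 = window
    tip = model.joint_positions(alpha_t[w0:w1])["fingertip"]
    speed = savgol_velocity(tip, cfg)
    peak = int(np.argmax(speed))
    onset = detect_onset(speed, peak).index
    contact = detect_contact(speed, peak).index
    onset_abs, peak_abs, contact_abs = w0 + onset, w0 + peak, w0 + contact
    excursions = {
        j: float(alpha_t[contact_abs, i] - alpha_t[onset_abs, i])
        for i, j in enumerate(JOINT_ORDER)}
    com = model.com_trajectory(alpha_t[[onset_abs, contact_abs]]).position
    centroid, _, ankle = _hand_centroid_and_head(
        model, alpha_t[[contact_abs]])
    hand = centroid[0] - ankle[0]
    return GroundTruth(
        onset_index=onset_abs, peak_index=peak_abs, contact_index=contact_abs,
        movement_time_ms=(contact_abs - onset_abs) / sample_rate * 1000.0,
        excursions=excursions, com_displacement=com[1] - com[0],
        hand_at_contact=hand)


def simulate_reach(dims: BodyDimensions, target, profile: StrategyProfile,
                   duration: float = 0.5, sample_rate: float = 100.0,
                   seed: int = 0, noise_std: float = DEFAULT_NOISE_STD,
                   model: BodyModel | None = None,
                   lead_in: float = 0.7, lead_out: float = 0.6) -> SimulatedTrial:
    """Simulate one reach to ``target`` and return markers plus ground truth.

    The reach interpolates from quiet standing to the solved contact posture
    along a minimum-jerk time course of ``duration`` seconds, padded with
    stationary lead-in/lead-out so the event detectors see quiet flanks.
    Marker noise is isotropic Gaussian with ``noise_std`` meters, seeded.
    """
    model = model or BodyModel(dims)
    alpha0 = model.standing_posture
    alpha_c = _contact_posture(model, target, profile)
    n_in = int(round(lead_in * sample_rate))
    n_out = int(round(lead_out * sample_rate))
    mj, _ = minimum_jerk(duration, sample_rate)
    alpha_t = np.concatenate([
        np.tile(alpha0, (n_in, 1)),
        alpha0 + mj[:, None] * (alpha_c - alpha0),
        np.tile(alpha_c, (n_out, 1))])
    markers = model.marker_positions(alpha_t)
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        markers = markers + rng.normal(0.0, noise_std, markers.shape)
    ts = TrajectorySet(list(model.marker_names), markers, sample_rate)
    gt = _ground_truth(model, alpha_t, sample_rate, (0, len(alpha_t)))
    return SimulatedTrial(trajectories=ts, ground_truth=gt,
                          contact_posture=alpha_c, start_posture=alpha0.copy(),
                          duration=duration)


def simulate_session(schedule, dims: BodyDimensions, profile: StrategyProfile,
                     seed: int = 0, sample_rate: float = 100.0,
                     duration: float = 0.5, noise_std: float = DEFAULT_NOISE_STD,
                     model: BodyModel | None = None,
                     interception_ap: float = 0.45,
                     dwell: float = 0.4, return_time: float = 0.8,
                     post_window: float = 0.5) -> SimulatedSession:
    """Simulate a whole game: one reach (or duck) per launched ball.

    Between trials the body holds quiet standing; each trial moves along a
    minimum-jerk program timed so contact coincides with the scheduled
    impact, holds the contact posture briefly, then returns.  Identical
    seeds give identical output.
    """
    model = model or BodyModel(dims)
    alpha0 = model.standing_posture
    launched = schedule.launched
    if not launched:
        raise ValueError("schedule has no launched balls")
    t_end = max(e.impact_time for e in launched) + dwell + return_time + 1.0
    n = int(round(t_end * sample_rate)) + 1
    alpha_t = np.tile(alpha0, (n, 1))
    mj, _ = minimum_jerk(duration, sample_rate)
    mj_back, _ = minimum_jerk(return_time, sample_rate)

    posture_cache: dict = {}
    trials_meta = []
    for e in launched:
        z = schedule.impact_height(e)
        key = (e.trial_type, round(z, 6))
        if key not in posture_cache:
            if e.trial_type == "duck":
                clearance = z - 0.12 - 0.05 - 0.05
                posture_cache[key] = _duck_posture(model, clearance)
            else:
                target = np.array([interception_ap, e.lateral_offset, z])
                posture_cache[key] = _contact_posture(model, target, profile)
        alpha_c = posture_cache[key]
        i_impact = int(round(e.impact_time * sample_rate))
        i_start = i_impact - (len(mj) - 1)
        if i_start < 0:
            raise ValueError("schedule starts too early for the reach duration")
        delta = alpha_c - alpha0
        alpha_t[i_start:i_impact + 1] = alpha0 + mj[:, None] * delta
        i_hold = min(i_impact + int(round(dwell * sample_rate)), n - 1)
        alpha_t[i_impact + 1:i_hold + 1] = alpha_c
        i_back_end = min(i_hold + len(mj_back) - 1, n - 1)
        m = i_back_end - i_hold + 1
        alpha_t[i_hold:i_back_end + 1] = alpha_c - mj_back[:m, None] * delta
        trials_meta.append((e, alpha_c, i_start, i_impact))

    markers = model.marker_positions(alpha_t)
    if noise_std > 0:
        rng = np.random.default_rng(seed)
        markers = markers + rng.normal(0.0, noise_std, markers.shape)
    ts = TrajectorySet(list(model.marker_names), markers, sample_rate)

    cfg = FilterConfig(sample_interval=1.0 / sample_rate)
    trials = []
    for e, alpha_c, i_start, i_impact in trials_meta:
        w0 = max(int(round(e.warning_time * sample_rate)), 0)
        w1 = min(int(round((e.impact_time + post_window) * sample_rate)) + 1, n)
        gt = _ground_truth(model, alpha_t, sample_rate, (w0, w1), cfg)
        trials.append(SimulatedTrial(
            trajectories=ts, ground_truth=gt, contact_posture=alpha_c,
            start_posture=alpha0.copy(), duration=duration,
            event_id=e.event_id, window=(w0, w1)))

    session = SimulatedSession(trajectories=ts, trials=trials,
                               schedule=schedule, model=model, profile=profile)
    centroid, head_top, _ = _hand_centroid_and_head(model, alpha_t)
    session._hand_centroid = centroid
    session._head_top = head_top
    return session
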