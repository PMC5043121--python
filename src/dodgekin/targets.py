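"""Individualized target locations, impact heights, and ball flight paths.

Standardized reach targets are placed in the mid-sagittal plane by a planar
two-link forward model: with the hips flexed by an angle ``theta`` from
vertical, the shoulder flexed 90 degrees and the elbow extended, the hand
lands at

    target = hip + trunk_length * (sin t, cos t) + arm_length * (cos t, -sin t)

in (AP, vertical) coordinates, with the hip joint at ``hip_height``.  The
high / middle / low targets correspond to 15, 30 and 60 degrees of hip
flexion.

The five game impact heights (IH0 highest ... IH4 lowest) are scaled per
participant: IH0 is eye height for every level, IH4 is the hand height the
forward model gives when the trunk adopts the baseline lumbar flexion
recorded for that level's standardized target (high -> Level 1, middle ->
Level 2, low -> Level 3), and IH1-IH3 are linearly interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BodyDimensions",
    "TargetSpec",
    "ImpactHeightSet",
    "LumbarBaseline",
    "BallPath",
    "STANDARD_HIP_FLEXIONS",
    "standardized_target_location",
    "recover_hip_flexion",
    "impact_heights_for_level",
    "ball_path",
]

#: hip-flexion angles (degrees) defining the high, middle and low targets
STANDARD_HIP_FLEXIONS = {"high": 15.0, "middle": 30.0, "low": 60.0}


@dataclass(frozen=True)
class BodyDimensions:
    """Participant body dimensions in meters."""

    hip_height: float
    trunk_length: float
    arm_length: float
    eye_height: float
    shin_height: float

    def __post_init__(self) -> None:
        vals = (self.hip_height, self.trunk_length, self.arm_length,
                self.eye_height, self.shin_height)
        if any(v <= 0 for v in vals):
            raise ValueError("all body dimensions must be positive")
        if not self.eye_height > self.hip_height > self.shin_height:
            raise ValueError("require eye_height > hip_height > shin_height")


@dataclass(frozen=True)
class TargetSpec:
    """Standardized-reach posture: hip flexion with shoulder at 90 degrees
    and the elbow extended."""

    hip_flexion_deg: float
    shoulder_flexion_deg: float = 90.0
    elbow_extended: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.hip_flexion_deg < 90.0:
            raise ValueError("hip flexion must be in (0, 90) degrees")


@dataclass(frozen=True)
class LumbarBaseline:
    """Mean lumbar flexion (degrees) used to reach each standardized target."""

    lumbar_flexion_high: float
    lumbar_flexion_mid: float
    lumbar_flexion_low: float

    def __post_init__(self) -> None:
        if not (self.lumbar_flexion_low >= self.lumbar_flexion_mid
                >= self.lumbar_flexion_high >= 0.0):
            raise ValueError("lumbar flexion must increase with target depth")

    def for_level(self, level: int) -> float:
        return {1: self.lumbar_flexion_high,
                2: self.lumbar_flexion_mid,
                3: self.lumbar_flexion_low}[level]


@dataclass(frozen=True)
class ImpactHeightSet:
    """Five vertical impact coordinates IH0..IH4 (m) for one game level."""

    level: int
    heights: tuple

    def __post_init__(self) -> None:
        if len(self.heights) != 5:
            raise ValueError("need five impact heights IH0..IH4")
        if not all(a > b for a, b in zip(self.heights, self.heights[1:])):
            raise ValueError("impact heights must be strictly decreasing")

    def __getitem__(self, index: int) -> float:
        return self.heights[index]


def _forward_hand(dims: BodyDimensions, theta_deg) -> tuple:
    """(AP, vertical) hand position of the standardized-reach linkage."""
    t = np.deg2rad(theta_deg)
    ap = dims.trunk_length * np.sin(t) + dims.arm_length * np.cos(t)
    vert = (dims.hip_height + dims.trunk_length * np.cos(t)
            - dims.arm_length * np.sin(t))
    return ap, vert


def standardized_target_location(dims: BodyDimensions,
                                 spec: TargetSpec) -> np.ndarray:
    """Mid-sagittal target point ``(AP, ML, vertical)`` in meters."""
    ap, vert = _forward_hand(dims, spec.hip_flexion_deg)
    return np.array([ap, 0.0, vert])


def recover_hip_flexion(dims: BodyDimensions, target: np.ndarray,
                        tol_deg: float = 1e-9) -> float:
    """Invert the standardized-reach construction: the hip-flexion angle in
    degrees that places the hand at ``target``.

    The hand's vertical coordinate is strictly decreasing in hip flexion on
    (0, 90) degrees, so the inverse is found by bracketed root-finding on the
    forward model; the AP coordinate is then cross-checked.
    """
    target = np.asarray(target, dtype=float)
    z = target[-1]
    lo, hi = 1e-12, 90.0 - 1e-12
    f = lambda th: _forward_hand(dims, th)[1] - z
    flo, fhi = f(lo), f(hi)
    if flo < 0:
        if flo > -1e-9:  # exactly-upright target, numerically at the boundary
            return 0.0
        raise ValueError("target is not reachable by the standardized posture")
    if fhi > 0:
        raise ValueError("target is not reachable by the standardized posture")
    theta = brentq(f, lo, hi, xtol=tol_deg)
    ap, _ = _forward_hand(dims, theta)
    if abs(ap - target[0]) > 1e-6:
        raise ValueError("target AP coordinate inconsistent with the "
                         "standardized-reach construction")
    return float(theta)


def impact_heights_for_level(
        dims: BodyDimensions, base: LumbarBaseline, level: int,
        lumbar_to_inclination: Callable[[float], float] | None = None,
) -> ImpactHeightSet:
    """Five impact heights for one game level.

    IH0 is eye height; IH4 is the forward-model hand height when the trunk
    adopts the level's baseline lumbar flexion (mapped to trunk inclination
    by ``lumbar_to_inclination``, identity by default); IH1-IH3 are linearly
    interpolated.  IH4 is floored at ``shin_height - 0.05`` m.
    """
    if level not in (1, 2, 3):
        raise ValueError("level must be 1, 2 or 3")
    mapping = lumbar_to_inclination or (lambda deg: deg)
    theta = mapping(base.for_level(level))
    theta = min(max(theta, 1e-9), 90.0 - 1e-9)
    _, ih4 = _forward_hand(dims, theta)
    ih4 = max(ih4, dims.shin_height - 0.05)
    ih0 = dims.eye_height
    if ih4 >= ih0:
        raise ValueError(
            f"computed IH4 ({ih4:.3f} m) is not below IH0 (eye height "
            f"{ih0:.3f} m)")
    heights = tuple(np.linspace(ih0, ih4, 5))
    return ImpactHeightSet(level=level, heights=heights)


@dataclass(frozen=True)
class BallPath:
    """Straight-line constant-speed ball flight from launch to impact."""

    origin: np.ndarray
    impact: np.ndarray
    flight_time: float

    def __call__(self, t) -> np.ndarray:
        """Ball center position at time ``t`` (seconds since launch)."""
        tau = np.clip(np.asarray(t, dtype=float) / self.flight_time, 0.0, 1.0)
        return self.origin + np.multiply.outer(tau, self.impact - self.origin)


def ball_path(impact_point: np.ndarray, lateral_offset: float,
              flight_time: float, launch_origin: np.ndarray) -> BallPath:
    """Parametric ball path hitting ``impact_point`` shifted laterally by
    ``lateral_offset`` (m, ML axis) at ``t = flight_time``."""
    if flight_time <= 0:
        raise ValueError("flight_time must be positive")
    impact = np.asarray(impact_point, dtype=float) + np.array(
        [0.0, lateral_offset, 0.0])
    return BallPath(origin=np.asarray(launch_origin, dtype=float),
                    impact=impact, flight_time=float(flight_time))
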