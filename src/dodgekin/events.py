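"""Savitzky-Golay smoothing/differentiation and threshold event detection.

The end-effector (right index fingertip) trajectory is smoothed with a
41-point fourth-order Savitzky-Golay filter at 100 Hz: at each interior
sample a quartic is fit by least squares to the sample and its 20 neighbors
on each side, and the fitted polynomial's derivative gives velocity.
Movement onset is found by searching backwards from peak speed for the last
sample at or below 5% of peak speed; target contact mirrors this with a
forward search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "FilterConfig",
    "ReachEvent",
    "DetectionResult",
    "savgol_smooth",
    "savgol_velocity",
    "detect_onset",
    "detect_contact",
    "movement_time",
]


@dataclass(frozen=True)
class FilterConfig:
    """Savitzky-Golay filter parameters.

    window_length:
        Number of samples in the local fit window (odd; default 41, i.e. the
        sample plus 20 neighbors on each side at 100 Hz).
    poly_order:
        Degree of the local least-squares polynomial (default 4).
    sample_interval:
        Sampling period in seconds (default 0.01 s).
    """

    window_length: int = 41
    poly_order: int = 4
    sample_interval: float = 0.01

    def __post_init__(self) -> None:
        if self.window_length % 2 != 1:
            raise ValueError("window_length must be odd")
        if not 0 <= self.poly_order < self.window_length:
            raise ValueError("poly_order must be < window_length")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")


@dataclass
class ReachEvent:
    """Onset / peak-speed / contact sample indices for one trial."""

    onset_index: int
    peak_index: int
    contact_index: int
    peak_speed: float

    def __post_init__(self) -> None:
        if not self.onset_index <= self.peak_index <= self.contact_index:
            raise ValueError("require onset <= peak <= contact")
        if not self.peak_speed > 0:
            raise ValueError("peak_speed must be positive")


class DetectionResult(NamedTuple):
    """Index of a threshold crossing plus whether the threshold was reached."""

    index: int
    found: bool


def _check_length(signal: np.ndarray, cfg: FilterConfig) -> None:
    if signal.shape[0] < cfg.window_length:
        raise ValueError(
            f"series of length {signal.shape[0]} is shorter than the "
            f"{cfg.window_length}-point filter window")


def savgol_smooth(signal: np.ndarray, cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """Savitzky-Golay smoothing of a scalar series.

    Interior samples take the value of the local least-squares polynomial at
    the window center.  Within half a window of each edge the polynomial
    fitted to the nearest full window is evaluated instead, so no samples
    are discarded.
    """
    signal = np.asarray(signal, dtype=float)
    _check_length(signal, cfg)
    return savgol_filter(signal, cfg.window_length, cfg.poly_order,
                         mode="interp", axis=0)


def savgol_derivative(signal: np.ndarray, cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """First derivative (units per second) from the local polynomial fit."""
    signal = np.asarray(signal, dtype=float)
    _check_length(signal, cfg)
    return savgol_filter(signal, cfg.window_length, cfg.poly_order,
                         deriv=1, delta=cfg.sample_interval,
                         mode="interp", axis=0)


def savgol_velocity(position: np.ndarray, cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """Speed series (m/s) of a 3D position series.

    Each axis is differentiated via the Savitzky-Golay polynomial
    coefficients; speed is the Euclidean norm of the velocity vector.
    """
    position = np.asarray(position, dtype=float)
    if position.ndim == 1:
        position = position[:, None]
    vel = savgol_derivative(position, cfg)
    return np.linalg.norm(vel, axis=1)


def detect_onset(speed: np.ndarray, peak_index: int,
                 fraction: float = 0.05) -> DetectionResult:
    """Movement onset: backwards search from the speed peak for the last
    sample with speed <= fraction * peak speed.

    Returns index 0 with ``found=False`` (and a warning) when the speed
    never drops to threshold before the peak.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size == 0:
        raise ValueError("empty speed series")
    if not 0 <= peak_index < speed.size:
        raise IndexError("peak_index out of range")
    threshold = fraction * speed[peak_index]
    below = np.flatnonzero(speed[:peak_index + 1] <= threshold)
    if below.size == 0:
        warnings.warn("speed never at/below threshold before peak; onset "
                      "clamped to sample 0", stacklevel=2)
        return DetectionResult(0, False)
    return DetectionResult(int(below[-1]), True)


def detect_contact(speed: np.ndarray, peak_index: int,
                   fraction: float = 0.05) -> DetectionResult:
    """Target contact: forward search from the speed peak for the first
    sample with speed <= fraction * peak speed.

    Returns the last index with ``found=False`` (and a warning) when speed
    never drops to threshold after the peak.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.size == 0:
        raise ValueError("empty speed series")
    if not 0 <= peak_index < speed.size:
        raise IndexError("peak_index out of range")
    threshold = fraction * speed[peak_index]
    below = np.flatnonzero(speed[peak_index:] <= threshold)
    if below.size == 0:
        warnings.warn("speed never at/below threshold after peak; contact "
                      "clamped to last sample", stacklevel=2)
        return DetectionResult(speed.size - 1, False)
    return DetectionResult(int(peak_index + below[0]), True)


def movement_time(ev: ReachEvent, sample_rate: float) -> float:
    """Movement time in milliseconds, onset to contact."""
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    return (ev.contact_index - ev.onset_index) / sample_rate * 1000.0
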