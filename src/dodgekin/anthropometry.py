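"""Whole-body center of mass from anthropometric segment parameters.

The body is modeled as 14 rigid segments (head+neck, trunk with pelvis
consolidated, and bilateral upper arms, forearms, hands, thighs, shanks,
feet).  Each segment's mass fraction of total body mass and the location of
its center of mass as a fraction of segment length from the proximal end
come from Winter's standard anthropometric tables, shipped as a CSV data
file (``data/winter_segments.csv``) and injectable so alternative parameter
sets can be used.

The whole-body COM is the mass-fraction-weighted mean of the segment COMs,
renormalized by the summed fractions of the segments actually modeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "AnthropometricTable",
    "COMTrajectory",
    "load_winter_table",
    "segment_com",
    "whole_body_com",
    "com_displacement",
]


@dataclass
class AnthropometricTable:
    """Per-segment mass fraction and COM location fraction.

    ``segments`` maps segment name -> (mass_fraction, com_location_fraction);
    the COM location is measured from the proximal endpoint.
    """

    segments: dict

    def __post_init__(self) -> None:
        total = 0.0
        for name, (mf, cf) in self.segments.items():
            if not (0.0 < mf < 1.0 and 0.0 < cf < 1.0):
                raise ValueError(f"segment {name!r}: fractions must be in (0, 1)")
            total += mf
        if not 0.99 <= total <= 1.01:
            raise ValueError(
                f"segment mass fractions sum to {total:.4f}, expected ~1")

    @property
    def total_mass_fraction(self) -> float:
        return sum(mf for mf, _ in self.segments.values())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnthropometricTable":
        return cls({row.segment: (row.mass_fraction, row.com_location_fraction)
                    for row in df.itertuples(index=False)})


def load_winter_table() -> AnthropometricTable:
    """Load the packaged Winter segment-parameter table."""
    with resources.files("dodgekin.data").joinpath("winter_segments.csv").open() as fh:
        df = pd.read_csv(fh)
    return AnthropometricTable.from_frame(df)


@dataclass
class COMTrajectory:
    """Whole-body COM position per frame, meters, in AP/ML/vertical axes."""

    position: np.ndarray  # (frames, 3)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.ndim != 2 or self.position.shape[1] != 3:
            raise ValueError("position must be (frames, 3)")

    @property
    def frame_count(self) -> int:
        return len(self.position)


def segment_com(proximal: np.ndarray, distal: np.ndarray,
                com_fraction: float) -> np.ndarray:
    """Segment COM: ``proximal + com_fraction * (distal - proximal)``.

    Accepts single points or per-frame arrays.  Coincident endpoints return
    the proximal point with a warning (zero-length segment).
    """
    if not 0.0 <= com_fraction <= 1.0:
        raise ValueError("com_fraction must be in [0, 1]")
    proximal = np.asarray(proximal, dtype=float)
    distal = np.asarray(distal, dtype=float)
    diff = distal - proximal
    if np.allclose(diff, 0.0):
        warnings.warn("segment has zero length; COM placed at proximal point",
                      stacklevel=2)
    return proximal + com_fraction * diff


def whole_body_com(segment_endpoints: dict,
                   table: AnthropometricTable) -> COMTrajectory:
    """Mass-fraction-weighted whole-body COM trajectory.

    Parameters
    ----------
    segment_endpoints:
        Maps segment name -> ``(proximal, distal)`` arrays of shape
        ``(frames, 3)`` (or ``(3,)`` for a static pose).
    table:
        Anthropometric parameters; every table segment must be present.
    """
    missing = [s for s in table.segments if s not in segment_endpoints]
    if missing:
        raise KeyError(f"segment endpoints missing for: {missing}")
    num = None
    total = 0.0
    for name, (mass_frac, com_frac) in table.segments.items():
        prox, dist = segment_endpoints[name]
        prox = np.atleast_2d(np.asarray(prox, dtype=float))
        dist = np.atleast_2d(np.asarray(dist, dtype=float))
        c = prox + com_frac * (dist - prox)
        num = mass_frac * c if num is None else num + mass_frac * c
        total += mass_frac
    return COMTrajectory(num / total)


def com_displacement(traj: COMTrajectory, ev) -> tuple:
    """COM displacement from movement onset to target contact,
    ``(AP, ML, vertical)`` in meters."""
    n = traj.frame_count
    if not (0 <= ev.onset_index < n and 0 <= ev.contact_index < n):
        raise IndexError("event indices outside trajectory")
    d = traj.position[ev.contact_index] - traj.position[ev.onset_index]
    return float(d[0]), float(d[1]), float(d[2])
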