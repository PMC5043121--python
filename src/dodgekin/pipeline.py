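"""Per-trial data reduction and condition-level summary tables.

For every launched ball the pipeline extracts the trial window (warning
time to impact + 0.5 s), smooths and differentiates the right index
fingertip with the Savitzky-Golay scheme, detects movement onset and target
contact at 5% of peak speed, and reports movement time, joint excursions
(contact minus onset angles by default), hand position at contact
referenced to the ankle centroid, and whole-body COM displacement along the
AP/ML/vertical axes.

Summaries stop at per-group means, standard deviations and paired condition
differences; inferential statistics are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anthropometry import com_displacement, whole_body_com
from .bodymodel import BodyModel
from .events import (FilterConfig, ReachEvent, detect_contact, detect_onset,
                     movement_time, savgol_velocity)
from .io_formats import TrajectorySet
from .kinematics import euler_decompose, fit_rigid_pose, joint_rotation

__all__ = [
    "ReductionConfig",
    "ReachRecord",
    "hand_at_contact",
    "run_pipeline",
    "records_to_frame",
    "summarize",
    "condition_difference",
]

MEASURES = ("movement_time_ms", "hand_ap", "hand_ml", "hand_vertical",
            "com_ap", "com_ml", "com_vertical")


@dataclass
class ReductionConfig:
    """Tunable parameters of the per-trial reduction."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    threshold_fraction: float = 0.05
    post_window: float = 0.5          # s past impact included in the search
    min_peak_speed: float = 0.15      # m/s; below this the trial is flagged
    excursion_reference: str = "onset"  # or "standing"
    fingertip_marker: str = "RFIN"

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.excursion_reference not in ("onset", "standing"):
            raise ValueError("excursion_reference must be 'onset' or 'standing'")


@dataclass
class ReachRecord:
    """Per-trial dependent measures."""

    trial_id: int
    condition: str
    level: int
    impact_height_index: int
    trial_type: str
    movement_time_ms: float = np.nan
    hand_at_contact: np.ndarray = None     # (AP, ML, vertical) m
    excursions: dict = field(default_factory=dict)  # joint -> deg
    com_displacement: np.ndarray = None    # (AP, ML, vertical) m
    onset_index: int = -1
    peak_index: int = -1
    contact_index: int = -1
    flags: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def hand_at_contact(ts: TrajectorySet, ev: ReachEvent,
                    hand_markers=("HAND1", "HAND2", "HAND3", "HAND4"),
                    left_hand_markers=("LHND1", "LHND2", "LHND3", "LHND4"),
                    ankle_markers=("RANK", "LANK")) -> np.ndarray:
    """Hand centroid at target contact, referenced to the ankle centroid.

    The centroid of the left and right hand marker clusters is adjusted by
    the centroid of the two ankle markers at the contact frame; the result
    is an (AP, ML, vertical) position in meters.
    """
    f = ev.contact_index
    right = ts.markers(hand_markers)[f].mean(axis=0)
    left = ts.markers(left_hand_markers)[f].mean(axis=0)
    ankles = ts.markers(ankle_markers)[f].mean(axis=0)
    hands = 0.5 * (right + left)
    if np.isnan(hands).any() or np.isnan(ankles).any():
        raise ValueError("hand or ankle markers missing at contact frame")
    return hands - ankles


def _segment_poses(ts: TrajectorySet, model: BodyModel) -> dict:
    return {c.segment_name: fit_rigid_pose(c, ts.markers(c.marker_names))
            for c in model.clusters}


def _joint_flexions(model: BodyModel, poses: dict) -> dict:
    """Flexion-extension series (deg) per joint from estimated poses."""
    out = {}
    for joint in model.chain:
        rel = joint_rotation(poses[joint.parent], poses[joint.child])
        angles, _ = euler_decompose(rel)
        out[joint.name] = joint.flexion_sign * angles[:, 0]
    return out


def run_pipeline(ts: TrajectorySet, schedule, model: BodyModel,
                 condition: str = "", cfg: ReductionConfig | None = None) -> list:
    """Reduce a session of marker data against its launch schedule.

    Returns one :class:`ReachRecord` per launched ball, in schedule order.
    Trials whose events cannot be detected are flagged, never dropped.
    """
    cfg = cfg or ReductionConfig()
    fs = ts.sample_rate
    poses = _segment_poses(ts, model)
    flexions = _joint_flexions(model, poses)
    com = whole_body_com(model.endpoints_from_poses(poses), model.table)
    fingertip = ts.marker(cfg.fingertip_marker)
    n = ts.frame_count
    filt = FilterConfig(cfg.filter.window_length, cfg.filter.poly_order,
                        1.0 / fs)

    records = []
    for e in schedule.launched:
        rec = ReachRecord(trial_id=e.event_id, condition=condition,
                          level=e.level,
                          impact_height_index=e.impact_height_index,
                          trial_type=e.trial_type)
        w0 = max(int(round(e.warning_time * fs)), 0)
        w1 = min(int(round((e.impact_time + cfg.post_window) * fs)) + 1, n)
        if w1 - w0 < filt.window_length:
            rec.flags.append("window_too_short")
            records.append(rec)
            continue
        tip = fingertip[w0:w1]
        if np.isnan(tip).any():
            rec.flags.append("fingertip_missing")
            records.append(rec)
            continue
        speed = savgol_velocity(tip, filt)
        peak = int(np.argmax(speed))
        if speed[peak] < cfg.min_peak_speed:
            rec.flags.append("undetectable")
            records.append(rec)
            continue
        onset = detect_onset(speed, peak, cfg.threshold_fraction)
        contact = detect_contact(speed, peak, cfg.threshold_fraction)
        if not onset.found:
            rec.flags.append("onset_not_found")
        if not contact.found:
            rec.flags.append("contact_not_found")
        ev = ReachEvent(onset_index=w0 + onset.index,
                        peak_index=w0 + peak,
                        contact_index=w0 + contact.index,
                        peak_speed=float(speed[peak]))
        rec.onset_index, rec.peak_index, rec.contact_index = \
            ev.onset_index, ev.peak_index, ev.contact_index
        rec.movement_time_ms = movement_time(ev, fs)
        ref = ev.onset_index if cfg.excursion_reference == "onset" else 0
        exc = {}
        for name, series in flexions.items():
            a0, a1 = series[ref], series[ev.contact_index]
            if np.isnan(a0) or np.isnan(a1):
                rec.flags.append(f"excursion_{name}_missing")
                exc[name] = np.nan
            else:
                exc[name] = float(a1 - a0)
        rec.excursions = exc
        try:
            rec.hand_at_contact = hand_at_contact(ts, ev)
        except (ValueError, KeyError):
            rec.flags.append("hand_at_contact_missing")
        d = com.position[ev.contact_index] - com.position[ev.onset_index]
        if np.isnan(d).any():
            rec.flags.append("com_missing")
        else:
            rec.com_displacement = d
        records.append(rec)
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Flatten reach records into a table (one row per trial)."""
    rows = []
    for r in records:
        row = {"trial_id": r.trial_id, "condition": r.condition,
               "level": r.level, "impact_height_index": r.impact_height_index,
               "trial_type": r.trial_type,
               "movement_time_ms": r.movement_time_ms,
               "ok": r.ok, "flags": ";".join(r.flags)}
        hand = r.hand_at_contact if r.hand_at_contact is not None \
            else (np.nan,) * 3
        com = r.com_displacement if r.com_displacement is not None \
            else (np.nan,) * 3
        row.update(hand_ap=hand[0], hand_ml=hand[1], hand_vertical=hand[2],
                   com_ap=com[0], com_ml=com[1], com_vertical=com[2])
        for joint, v in r.excursions.items():
            row[f"exc_{joint}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(records, group_by=("condition", "impact_height_index")) -> pd.DataFrame:
    """Mean, SD and count per measure per group.

    ``records`` may be a list of :class:`ReachRecord` or an equivalent
    DataFrame.  Groups of size one report SD 0 with ``sd_defined`` False.
    Flagged trials are excluded (their exclusions remain visible in the
    record table).
    """
    df = records if isinstance(records, pd.DataFrame) \
        else records_to_frame(records)
    df = df[df["ok"]] if "ok" in df else df
    if df.empty:
        raise ValueError("no unflagged records to summarize")
    measures = [c for c in df.columns
                if c in MEASURES or c.startswith("exc_")]
    rows = []
    for key, g in df.groupby(list(group_by)):
        key = key if isinstance(key, tuple) else (key,)
        for m in measures:
            vals = g[m].dropna().to_numpy()
            if vals.size == 0:
                continue
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
            rows.append(dict(zip(group_by, key), measure=m,
                             mean=float(vals.mean()), sd=sd,
                             count=int(vals.size),
                             sd_defined=vals.size > 1))
    return pd.DataFrame(rows)


def condition_difference(records, cond_a: str, cond_b: str,
                         group_by=("impact_height_index",)) -> pd.DataFrame:
    """Per-measure mean differences (cond_a minus cond_b) by group."""
    summary = summarize(records, group_by=("condition",) + tuple(group_by))
    a = summary[summary["condition"] == cond_a]
    b = summary[summary["condition"] == cond_b]
    keys = list(group_by) + ["measure"]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    merged["difference"] = merged["mean_a"] - merged["mean_b"]
    return merged[keys + ["mean_a", "mean_b", "difference"]]
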