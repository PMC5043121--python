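"""Rigid segment pose estimation and Euler joint-angle decomposition.

Segment poses are recovered per frame from clusters of at least three
non-collinear markers by a closed-form least-squares (Kabsch / orthogonal
Procrustes) fit with a reflection guard.  Inter-segment rotations are
decomposed with the intrinsic Euler sequence used throughout the package:

1. flexion-extension about the parent ML axis (+y),
2. lateral bending about the parent AP axis (+x),
3. axial rotation about the parent vertical axis (+z),

i.e. an intrinsic Y-X-Z sequence in the canonical AP/ML/vertical frame.
The sequence order follows the standard biomechanical convention
(flexion first, axial rotation last); intrinsic rotation about parent
axes is a documented package choice and is configurable via ``sequence``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "MarkerCluster",
    "SegmentPose",
    "JointAngleSeries",
    "JointDefinition",
    "GimbalWarning",
    "DegenerateGeometryError",
    "fit_rigid_pose",
    "joint_rotation",
    "euler_compose",
    "euler_decompose",
    "compute_joint_angles",
]

#: intrinsic axes for (flexion, lateral bending, axial rotation)
DEFAULT_SEQUENCE = "YXZ"

JOINT_NAMES = ("ankle", "knee", "hip", "spine", "shoulder", "elbow")


class GimbalWarning(UserWarning):
    """Middle Euler angle within 0.5 degrees of +/-90: decomposition ill-posed."""


class DegenerateGeometryError(ValueError):
    """Marker configuration is collinear or otherwise rank-deficient."""


def _collinear(points: np.ndarray, tol: float = 1e-10) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


@dataclass
class MarkerCluster:
    """Rigid cluster of markers attached to one body segment.

    ``template_points`` are the marker coordinates in the segment frame
    (meters); ``marker_names`` are the trajectory-set identifiers in the same
    order.
    """

    segment_name: str
    marker_names: list
    template_points: np.ndarray

    def __post_init__(self) -> None:
        self.template_points = np.asarray(self.template_points, dtype=float)
        if self.template_points.shape != (len(self.marker_names), 3):
            raise ValueError("template_points must be (n_markers, 3)")
        if len(self.marker_names) < 3:
            raise ValueError("a cluster needs at least 3 markers")
        if _collinear(self.template_points):
            raise DegenerateGeometryError(
                f"cluster {self.segment_name!r}: template points are collinear")


@dataclass
class SegmentPose:
    """Per-frame rigid transform of a segment: x_world = R @ x_segment + t."""

    rotations: np.ndarray   # (frames, 3, 3)
    translations: np.ndarray  # (frames, 3)
    valid: np.ndarray = None  # (frames,) bool

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.rotations), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.rotations.shape[1:] != (3, 3):
            raise ValueError("rotations must be (frames, 3, 3)")
        if self.translations.shape != (len(self.rotations), 3):
            raise ValueError("translations must be (frames, 3)")
        R = self.rotations[self.valid]
        if len(R):
            err = np.abs(R @ np.swapaxes(R, 1, 2) - np.eye(3)).max()
            if err > 1e-8:
                raise ValueError(f"rotations not orthonormal (max dev {err:.2e})")
            if (np.linalg.det(R) < 0).any():
                raise ValueError("rotations must be proper (det +1)")

    @property
    def frame_count(self) -> int:
        return len(self.rotations)

    def transform_points(self, local: np.ndarray) -> np.ndarray:
        """Map segment-frame points ``(k, 3)`` to world, ``(frames, k, 3)``."""
        local = np.atleast_2d(local)
        out = np.einsum("fij,kj->fki", self.rotations, local) \
            + self.translations[:, None, :]
        out[~self.valid] = np.nan
        return out


@dataclass
class JointAngleSeries:
    """Euler joint angles in degrees per frame for one joint."""

    joint_name: str
    flexion_extension: np.ndarray
    lateral_bending: np.ndarray
    axial_rotation: np.ndarray
    valid: np.ndarray = None

    def __post_init__(self) -> None:
        self.flexion_extension = np.asarray(self.flexion_extension, dtype=float)
        self.lateral_bending = np.asarray(self.lateral_bending, dtype=float)
        self.axial_rotation = np.asarray(self.axial_rotation, dtype=float)
        n = len(self.flexion_extension)
        if len(self.lateral_bending) != n or len(self.axial_rotation) != n:
            raise ValueError("angle components must have equal length")
        if self.valid is None:
            self.valid = ~np.isnan(self.flexion_extension)

    @property
    def frame_count(self) -> int:
        return len(self.flexion_extension)


@dataclass
class JointDefinition:
    """Parent/child segments forming a joint.

    ``flexion_sign`` maps the decomposed flexion-extension angle onto the
    joint's anatomically positive direction (e.g. knee flexion is a negative
    rotation of the thigh relative to the shank about +ML).
    """

    name: str
    parent: str
    child: str
    flexion_sign: float = 1.0


def fit_rigid_pose(template: MarkerCluster, observed: np.ndarray) -> SegmentPose:
    """Least-squares rigid transform mapping the cluster template onto the
    observed markers, frame by frame.

    Parameters
    ----------
    template:
        Cluster with ``k`` template points in the segment frame.
    observed:
        Observed marker positions, shape ``(frames, k, 3)`` (a single frame
        ``(k, 3)`` is promoted).  NaN marks missing markers; frames with
        fewer than three valid markers are flagged invalid rather than
        raising.

    Returns
    -------
    SegmentPose
        ``R @ template + t`` is the least-squares fit to the observations;
        reflections are rejected (det(R) = +1 always).
    """
    observed = np.asarray(observed, dtype=float)
    if observed.ndim == 2:
        observed = observed[None]
    k = len(template.marker_names)
    if observed.shape[1:] != (k, 3):
        raise ValueError(f"observed must be (frames, {k}, 3)")
    n = observed.shape[0]
    tpl = template.template_points
    ok = ~np.isnan(observed).any(axis=2)  # (frames, k)
    full = ok.all(axis=1)
    R = np.full((n, 3, 3), np.nan)
    t = np.full((n, 3), np.nan)
    valid = np.zeros(n, dtype=bool)

    if full.any():
        obs = observed[full]
        Rf, tf = _kabsch_batch(tpl, obs)
        R[full], t[full] = Rf, tf
        valid[full] = True

    # frames with some (but >=3 non-collinear) markers: fit on the subset
    for f in np.flatnonzero(~full):
        idx = np.flatnonzero(ok[f])
        if len(idx) < 3 or _collinear(tpl[idx]):
            continue
        Rf, tf = _kabsch_batch(tpl[idx], observed[f, idx][None])
        R[f], t[f] = Rf[0], tf[0]
        valid[f] = True

    return SegmentPose(np.where(valid[:, None, None], R, np.eye(3)),
                       np.nan_to_num(t), valid)


def _kabsch_batch(template: np.ndarray, observed: np.ndarray):
    """Batched Kabsch fit: returns (R, t) with R @ template + t ~= observed."""
    tpl_c = template - template.mean(axis=0)
    obs_mean = observed.mean(axis=1)
    obs_c = observed - obs_mean[:, None, :]
    H = np.einsum("ki,fkj->fij", tpl_c, obs_c)  # (frames, 3, 3)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.swapaxes(Vt, 1, 2) @ np.swapaxes(U, 1, 2)))
    D = np.zeros_like(H)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = np.swapaxes(Vt, 1, 2) @ D @ np.swapaxes(U, 1, 2)
    t = obs_mean - np.einsum("fij,j->fi", R, template.mean(axis=0))
    return R, t


def joint_rotation(parent: SegmentPose, child: SegmentPose) -> np.ndarray:
    """Rotation of the child segment expressed in the parent frame,
    ``R_rel = R_parent^T R_child`` per frame.  Frames invalid in either pose
    come back as NaN."""
    if parent.frame_count != child.frame_count:
        raise ValueError("parent and child must have equal frame counts")
    rel = np.swapaxes(parent.rotations, 1, 2) @ child.rotations
    bad = ~(parent.valid & child.valid)
    rel[bad] = np.nan
    return rel


def euler_compose(flexion: float, lateral: float, axial: float,
                  sequence: str = DEFAULT_SEQUENCE) -> np.ndarray:
    """Compose a rotation matrix from the intrinsic Euler triple (degrees)."""
    return Rotation.from_euler(
        sequence, np.stack(np.broadcast_arrays(flexion, lateral, axial), axis=-1),
        degrees=True).as_matrix()


def euler_decompose(rotation: np.ndarray, sequence: str = DEFAULT_SEQUENCE,
                    gimbal_tol_deg: float = 0.5):
    """Decompose proper rotation matrices into the intrinsic Euler triple
    (flexion-extension, lateral bending, axial rotation), degrees.

    Returns ``(angles, gimbal)`` where ``angles`` has shape ``(..., 3)`` and
    ``gimbal`` flags frames whose middle angle is within ``gimbal_tol_deg``
    of +/-90 degrees.  A :class:`GimbalWarning` is issued if any frame is
    flagged.  NaN frames pass through as NaN.
    """
    rotation = np.asarray(rotation, dtype=float)
    single = rotation.ndim == 2
    mats = rotation[None] if single else rotation
    nanframes = np.isnan(mats).any(axis=(1, 2))
    out = np.full(mats.shape[:1] + (3,), np.nan)
    if (~nanframes).any():
        good = mats[~nanframes]
        err = np.abs(good @ np.swapaxes(good, 1, 2) - np.eye(3)).max()
        if err > 1e-6 or (np.linalg.det(good) < 0).any():
            raise ValueError("input is not a proper rotation matrix")
        with warnings.catch_warnings():
            # scipy warns on exact gimbal lock; we flag it ourselves
            warnings.simplefilter("ignore")
            out[~nanframes] = Rotation.from_matrix(good).as_euler(
                sequence, degrees=True)
    gimbal = np.abs(np.abs(out[..., 1]) - 90.0) <= gimbal_tol_deg
    gimbal &= ~np.isnan(out[..., 1])
    if gimbal.any():
        warnings.warn("Euler decomposition near gimbal lock", GimbalWarning,
                      stacklevel=2)
    if single:
        return out[0], bool(gimbal[0])
    return out, gimbal


def compute_joint_angles(ts, clusters, chain,
                         sequence: str = DEFAULT_SEQUENCE) -> list:
    """Derive joint-angle time series from marker trajectories.

    Parameters
    ----------
    ts : TrajectorySet
        Marker data containing every cluster marker.
    clusters : iterable of MarkerCluster
        One cluster per segment appearing in ``chain``.
    chain : iterable of JointDefinition
        Parent-child joints to decompose.

    Returns
    -------
    list of JointAngleSeries, one per joint, in chain order.  Frames whose
    parent or child pose is unresolvable carry NaN angles.
    """
    by_segment = {c.segment_name: c for c in clusters}
    poses = {}
    needed = {j.parent for j in chain} | {j.child for j in chain}
    for seg in needed:
        if seg not in by_segment:
            raise KeyError(f"no marker cluster configured for segment {seg!r}")
        cluster = by_segment[seg]
        missing = [m for m in cluster.marker_names if m not in ts.marker_names]
        if missing:
            raise KeyError(
                f"segment {seg!r}: markers {missing} absent from trajectories")
        observed = ts.markers(cluster.marker_names)
        poses[seg] = fit_rigid_pose(cluster, observed)

    series = []
    for joint in chain:
        rel = joint_rotation(poses[joint.parent], poses[joint.child])
        angles, _ = euler_decompose(rel, sequence=sequence)
        series.append(JointAngleSeries(
            joint_name=joint.name,
            flexion_extension=joint.flexion_sign * angles[:, 0],
            lateral_bending=angles[:, 1],
            axial_rotation=angles[:, 2],
        ))
    return series
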