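"""Sagittal-plane full-body linkage with rigid marker clusters.

The model chains foot - shank - thigh - pelvis - trunk (with a rigid head) -
upper arm - forearm - hand in the mid-sagittal plane.  Six joint angles
drive it, in degrees, ordered

    (ankle, knee, hip, spine, shoulder, elbow)

with anatomically positive directions: ankle dorsiflexion tilts the shank
forward, knee flexion folds the thigh backward relative to the shank, hip
and spine flexion tilt pelvis and trunk forward, shoulder flexion raises
the arm forward from its hanging position, and elbow flexion folds the
forearm forward/up.  Zero everywhere is quiet upright standing.

Segment lengths derive from the participant's body dimensions plus Winter's
length fractions of stature where a dimension is not measured directly
(knee and ankle heights from hip height, arm segment splits from total arm
length).  Each segment carries a four-marker rigid cluster whose template
coordinates are expressed in the segment frame; world marker positions are
produced by the segment pose, which is what the pose-estimation pipeline
inverts.  Analyses track the right side; the left ankle and hand markers
required by the hand-centroid convention are mirrored across the
mid-sagittal plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anthropometry import AnthropometricTable, load_winter_table, whole_body_com
from .kinematics import JointDefinition, MarkerCluster
from .targets import BodyDimensions

__all__ = ["BodyModel", "JOINT_ORDER", "STANDING_POSTURE"]

JOINT_ORDER = ("ankle", "knee", "hip", "spine", "shoulder", "elbow")

#: quiet standing holding the ball in front: slight shoulder/elbow flexion
STANDING_POSTURE = np.array([0.0, 0.0, 0.0, 0.0, 30.0, 20.0])

# stature fractions (Winter): vertical heights of landmarks
_HIP_OF_STATURE = 0.530
_KNEE_OF_STATURE = 0.285
_ANKLE_OF_STATURE = 0.039
_FOOT_LENGTH_OF_STATURE = 0.152
# arm-length split into upper arm / forearm / hand
_ARM_SPLIT = (0.43, 0.33, 0.24)
# pelvis (hip to L5/S1) share of the hip-to-shoulder trunk line
_PELVIS_OF_TRUNK = 0.30

_MARKER_PERP = np.array([
    [0.050, 0.025], [-0.040, 0.050], [0.060, -0.035], [-0.050, -0.040]])
_MARKER_AXIAL = np.array([0.20, 0.40, 0.60, 0.80])


def _rot_y(angle_deg: np.ndarray) -> np.ndarray:
    """Rotation about the ML (+y) axis; positive rotates +z toward +x."""
    a = np.deg2rad(np.asarray(angle_deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    R = np.zeros(a.shape + (3, 3))
    R[..., 0, 0] = c
    R[..., 0, 2] = s
    R[..., 1, 1] = 1.0
    R[..., 2, 0] = -s
    R[..., 2, 2] = c
    return R


@dataclass
class BodyModel:
    """Participant-scaled linkage, marker templates and joint chain."""

    dims: BodyDimensions
    standing_posture: np.ndarray = None
    table: AnthropometricTable = None

    def __post_init__(self) -> None:
        if self.standing_posture is None:
            self.standing_posture = STANDING_POSTURE.copy()
        if self.table is None:
            self.table = load_winter_table()
        d = self.dims
        stature = d.hip_height / _HIP_OF_STATURE
        self.ankle_height = _ANKLE_OF_STATURE * stature
        knee_height = _KNEE_OF_STATURE * stature
        self.len_shank = knee_height - self.ankle_height
        self.len_thigh = d.hip_height - knee_height
        self.len_pelvis = _PELVIS_OF_TRUNK * d.trunk_length
        self.len_thorax = d.trunk_length - self.len_pelvis
        shoulder_height = d.hip_height + d.trunk_length
        self.len_head = max(d.eye_height + 0.12 - shoulder_height, 0.15)
        self.len_upper_arm = _ARM_SPLIT[0] * d.arm_length
        self.len_forearm = _ARM_SPLIT[1] * d.arm_length
        self.len_hand = _ARM_SPLIT[2] * d.arm_length
        self.len_foot = _FOOT_LENGTH_OF_STATURE * stature
        self._build_clusters()
        self.chain = [
            JointDefinition("ankle", "foot", "shank", +1.0),
            JointDefinition("knee", "shank", "thigh", -1.0),
            JointDefinition("hip", "thigh", "pelvis", +1.0),
            JointDefinition("spine", "pelvis", "trunk", +1.0),
            JointDefinition("shoulder", "trunk", "upper_arm", -1.0),
            JointDefinition("elbow", "upper_arm", "forearm", -1.0),
        ]

    # ------------------------------------------------------------ clusters

    def _build_clusters(self) -> None:
        # local distal endpoint of each segment (z along the segment axis;
        # arm segments point to -z because their frame angle is measured
        # relative to the hanging direction)
        self.segment_distal = {
            "foot": np.array([self.len_foot, 0.0, -self.ankle_height]),
            "shank": np.array([0.0, 0.0, self.len_shank]),
            "thigh": np.array([0.0, 0.0, self.len_thigh]),
            "pelvis": np.array([0.0, 0.0, self.len_pelvis]),
            "trunk": np.array([0.0, 0.0, self.len_thorax]),
            "head": np.array([0.0, 0.0, self.len_head]),
            "upper_arm": np.array([0.0, 0.0, -self.len_upper_arm]),
            "forearm": np.array([0.0, 0.0, -self.len_forearm]),
            "hand": np.array([0.0, 0.0, -self.len_hand]),
        }
        self.clusters = []
        for seg, distal in self.segment_distal.items():
            pts = np.outer(_MARKER_AXIAL, distal)
            pts[:, 0] += _MARKER_PERP[:, 0]
            pts[:, 1] += _MARKER_PERP[:, 1]
            names = [f"{seg.upper()}{i}" for i in range(1, 5)]
            self.clusters.append(MarkerCluster(seg, names, pts))
        self.cluster_by_segment = {c.segment_name: c for c in self.clusters}
        # extra point markers: right fingertip, ankle joints, mirrored left hand
        self.fingertip_local = self.segment_distal["hand"]
        self.extra_markers = ["RFIN", "RANK", "LANK"] + \
            [f"LHND{i}" for i in range(1, 5)]
        self.marker_names = [m for c in self.clusters for m in c.marker_names] \
            + self.extra_markers

    # ------------------------------------------------------------ kinematics

    def frame_angles(self, alpha: np.ndarray) -> dict:
        """Absolute segment-frame angles (deg about ML) from joint angles."""
        alpha = np.asarray(alpha, dtype=float)
        a = {name: alpha[..., i] for i, name in enumerate(JOINT_ORDER)}
        shank = a["ankle"]
        thigh = shank - a["knee"]
        pelvis = thigh + a["hip"]
        trunk = pelvis + a["spine"]
        upper_arm = trunk - a["shoulder"]
        forearm = upper_arm - a["elbow"]
        zeros = np.zeros_like(shank)
        return {"foot": zeros, "shank": shank, "thigh": thigh,
                "pelvis": pelvis, "trunk": trunk, "head": trunk,
                "upper_arm": upper_arm, "forearm": forearm, "hand": forearm}

    @staticmethod
    def _unit(angle_deg: np.ndarray) -> np.ndarray:
        """World direction of a segment's +z axis at frame angle ``angle``."""
        a = np.deg2rad(np.asarray(angle_deg, dtype=float))
        return np.stack([np.sin(a), np.zeros_like(a), np.cos(a)], axis=-1)

    def joint_positions(self, alpha: np.ndarray) -> dict:
        """World positions of the joints and key landmarks.

        ``alpha`` has shape ``(..., 6)``; every returned array has shape
        ``(..., 3)``.  The ankle is fixed at the origin (AP = ML = 0) at
        ankle height; arm segments hang from the shoulder.
        """
        alpha = np.asarray(alpha, dtype=float)
        ang = self.frame_angles(alpha)
        ankle = np.zeros(alpha.shape[:-1] + (3,))
        ankle[..., 2] = self.ankle_height
        knee = ankle + self.len_shank * self._unit(ang["shank"])
        hip = knee + self.len_thigh * self._unit(ang["thigh"])
        l5 = hip + self.len_pelvis * self._unit(ang["pelvis"])
        shoulder = l5 + self.len_thorax * self._unit(ang["trunk"])
        head_top = shoulder + self.len_head * self._unit(ang["trunk"])
        # arm frame angle is relative to hanging (-z), so distal is at
        # angle + 180 in world terms
        elbow = shoulder + self.len_upper_arm * self._unit(ang["upper_arm"] + 180.0)
        wrist = elbow + self.len_forearm * self._unit(ang["forearm"] + 180.0)
        fingertip = wrist + self.len_hand * self._unit(ang["forearm"] + 180.0)
        toe = ankle + np.array([self.len_foot, 0.0, -0.0])
        toe = toe - np.array([0.0, 0.0, self.ankle_height])
        return {"ankle": ankle, "knee": knee, "hip": hip, "l5": l5,
                "shoulder": shoulder, "head_top": head_top, "elbow": elbow,
                "wrist": wrist, "fingertip": fingertip, "toe": toe}

    def segment_poses(self, alpha: np.ndarray) -> dict:
        """Ground-truth segment poses: maps segment -> (R, origin)."""
        ang = self.frame_angles(alpha)
        pos = self.joint_positions(alpha)
        origins = {"foot": pos["ankle"], "shank": pos["ankle"],
                   "thigh": pos["knee"], "pelvis": pos["hip"],
                   "trunk": pos["l5"], "head": pos["shoulder"],
                   "upper_arm": pos["shoulder"], "forearm": pos["elbow"],
                   "hand": pos["wrist"]}
        return {seg: (_rot_y(ang[seg]), origins[seg]) for seg in origins}

    def marker_positions(self, alpha: np.ndarray) -> np.ndarray:
        """Noiseless world marker positions, shape ``(frames, n_markers, 3)``,
        in the order of :attr:`marker_names`."""
        alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
        poses = self.segment_poses(alpha)
        pos = self.joint_positions(alpha)
        blocks = []
        hand_world = None
        for cluster in self.clusters:
            R, origin = poses[cluster.segment_name]
            world = np.einsum("fij,kj->fki", R, cluster.template_points) \
                + origin[:, None, :]
            if cluster.segment_name == "hand":
                hand_world = world
            blocks.append(world)
        R_hand, origin_hand = poses["hand"]
        rfin = (np.einsum("fij,j->fi", R_hand, self.fingertip_local)
                + origin_hand)[:, None, :]
        rank = pos["ankle"][:, None, :] + np.array([0.0, -0.05, 0.0])
        lank = pos["ankle"][:, None, :] + np.array([0.0, +0.05, 0.0])
        lhnd = hand_world * np.array([1.0, -1.0, 1.0])  # mirror across ML=0
        return np.concatenate(blocks + [rfin, rank, lank, lhnd], axis=1)

    # ------------------------------------------------------------ COM support

    #: anthropometric segment -> (proximal landmark, distal landmark);
    #: left-side segments reuse the right-side chain (mid-sagittal symmetry)
    COM_ENDPOINTS = {
        "head_neck": ("shoulder", "head_top"),
        "trunk": ("hip", "shoulder"),
        "upper_arm_r": ("shoulder", "elbow"),
        "upper_arm_l": ("shoulder", "elbow"),
        "forearm_r": ("elbow", "wrist"),
        "forearm_l": ("elbow", "wrist"),
        "hand_r": ("wrist", "fingertip"),
        "hand_l": ("wrist", "fingertip"),
        "thigh_r": ("hip", "knee"),
        "thigh_l": ("hip", "knee"),
        "shank_r": ("knee", "ankle"),
        "shank_l": ("knee", "ankle"),
        "foot_r": ("ankle", "toe"),
        "foot_l": ("ankle", "toe"),
    }

    #: anthropometric segment -> ((frame segment, local point) proximal,
    #: (frame segment, local point) distal); each endpoint is expressed in
    #: the frame of the segment whose pose locates it rigidly
    def endpoint_locals(self) -> dict:
        z = np.zeros(3)
        d = self.segment_distal
        arm = {
            "upper_arm": (("upper_arm", z), ("upper_arm", d["upper_arm"])),
            "forearm": (("forearm", z), ("forearm", d["forearm"])),
            "hand": (("hand", z), ("hand", d["hand"])),
        }
        out = {
            "head_neck": (("head", z), ("head", d["head"])),
            # anthropometric trunk spans hip to shoulder; the two endpoints
            # ride on the pelvis and thorax segments respectively
            "trunk": (("pelvis", z), ("trunk", d["trunk"])),
            # thigh/shank COM fractions are measured from the proximal
            # (hip / knee) end, the distal end of this ankle-rooted chain
            "thigh_r": (("thigh", d["thigh"]), ("thigh", z)),
            "thigh_l": (("thigh", d["thigh"]), ("thigh", z)),
            "shank_r": (("shank", d["shank"]), ("shank", z)),
            "shank_l": (("shank", d["shank"]), ("shank", z)),
            "foot_r": (("foot", z), ("foot", d["foot"])),
            "foot_l": (("foot", z), ("foot", d["foot"])),
        }
        for seg, spec in arm.items():
            out[f"{seg}_r"] = spec
            out[f"{seg}_l"] = spec
        return out

    def com_trajectory(self, alpha: np.ndarray):
        """Ground-truth whole-body COM from the joint-angle program."""
        pos = self.joint_positions(np.atleast_2d(np.asarray(alpha, float)))
        endpoints = {}
        for seg, (prox, dist) in self.COM_ENDPOINTS.items():
            p, q = pos[prox], pos[dist]
            # Winter measures the thigh/shank COM from the proximal (hip/
            # knee) end, which is the distal end of our ankle-rooted chain
            endpoints[seg] = (p, q)
        return whole_body_com(endpoints, self.table)

    def endpoints_from_poses(self, poses: dict) -> dict:
        """Segment endpoint world trajectories from estimated poses.

        ``poses`` maps frame-segment name -> SegmentPose (as recovered by
        the marker pipeline); returns the anthropometric endpoint mapping
        consumed by :func:`~dodgekin.anthropometry.whole_body_com`.
        """
        out = {}
        for seg, ((seg_p, loc_p), (seg_d, loc_d)) in self.endpoint_locals().items():
            prox = poses[seg_p].transform_points(loc_p)[:, 0, :]
            dist = poses[seg_d].transform_points(loc_d)[:, 0, :]
            out[seg] = (prox, dist)
        return out
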