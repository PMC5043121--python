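import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import dodgekin as dk
from dodgekin.kinematics import (DegenerateGeometryError, GimbalWarning,
                                 euler_compose, euler_decompose,
                                 fit_rigid_pose, joint_rotation)

TEMPLATE = dk.MarkerCluster(
    "seg", ["a", "b", "c", "d"],
    np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0],
              [0.0, 0.08, 0.0], [0.02, 0.03, 0.09]]))


def _pose_of(R, t):
    return dk.SegmentPose(R[None], np.asarray(t, float)[None])


# --------------------------------------------------------------- rigid fit

def test_identity_fit():
    pose = fit_rigid_pose(TEMPLATE, TEMPLATE.template_points)
    np.testing.assert_allclose(pose.rotations[0], np.eye(3), atol=1e-12)
    np.testing.assert_allclose(pose.translations[0], 0.0, atol=1e-12)


def test_known_transform_recovered_to_1e9():
    R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
    t = np.array([0.1, 0.0, 0.0])
    obs = TEMPLATE.template_points @ R.T + t
    pose = fit_rigid_pose(TEMPLATE, obs)
    assert np.abs(pose.rotations[0] - R).max() < 1e-9
    assert np.abs(pose.translations[0] - t).max() < 1e-9


def test_monte_carlo_rotation_error_under_noise(rng):
    # well-conditioned (tetrahedral, 12 cm circumradius) four-marker cluster
    tpl = dk.MarkerCluster(
        "seg", list("abcd"),
        0.12 * np.array([[1, 1, 1], [1, -1, -1],
                         [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3))
    R = Rotation.from_euler("YXZ", [25, 10, -40], degrees=True).as_matrix()
    t = np.array([0.3, -0.2, 1.1])
    clean = tpl.template_points @ R.T + t
    obs = clean[None] + rng.normal(0, 0.001, (1000, 4, 3))
    pose = fit_rigid_pose(tpl, obs)
    rel = pose.rotations @ R.T
    ang = Rotation.from_matrix(rel).magnitude() * 180 / np.pi
    assert np.median(ang) < 0.5


def test_reflection_guard_keeps_det_positive(rng):
    # near-planar noisy cluster: naive SVD can flip to a reflection
    tpl = dk.MarkerCluster("flat", ["a", "b", "c"], np.array(
        [[0.0, 0.0, 0.0], [0.1, 0.0, 0.0], [0.0, 0.1, 1e-6]]))
    obs = tpl.template_points[None] + rng.normal(0, 0.01, (200, 3, 3))
    pose = fit_rigid_pose(tpl, obs)
    assert np.all(np.linalg.det(pose.rotations[pose.valid]) > 0.999)


def test_equivariance_under_rigid_transform(rng):
    obs = TEMPLATE.template_points + rng.normal(0, 0.002, (4, 3))
    base = fit_rigid_pose(TEMPLATE, obs)
    T_R = Rotation.from_euler("XYZ", [17, -33, 8], degrees=True).as_matrix()
    T_t = np.array([0.5, 1.0, -0.3])
    moved = obs @ T_R.T + T_t
    pose = fit_rigid_pose(TEMPLATE, moved)
    np.testing.assert_allclose(pose.rotations[0], T_R @ base.rotations[0],
                               atol=1e-9)
    np.testing.assert_allclose(pose.translations[0],
                               T_R @ base.translations[0] + T_t, atol=1e-9)


def test_too_few_markers_flags_frame():
    obs = np.tile(TEMPLATE.template_points, (3, 1, 1))
    obs[1, 2:, :] = np.nan  # only two valid markers in frame 1
    pose = fit_rigid_pose(TEMPLATE, obs)
    assert list(pose.valid) == [True, False, True]


def test_collinear_template_rejected():
    with pytest.raises(DegenerateGeometryError):
        dk.MarkerCluster("bad", ["a", "b", "c"],
                         np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float))


# --------------------------------------------------------- joint rotation

def test_joint_rotation_identity_and_definition():
    R = Rotation.from_euler("Y", 40, degrees=True).as_matrix()
    eye = _pose_of(np.eye(3), [0, 0, 0])
    child = _pose_of(R, [1, 0, 0])
    np.testing.assert_allclose(joint_rotation(eye, eye)[0], np.eye(3),
                               atol=1e-12)
    np.testing.assert_allclose(joint_rotation(eye, child)[0], R, atol=1e-12)


def test_joint_rotation_composition_round_trip(rng):
    Rp = Rotation.random(50, random_state=7).as_matrix()
    Rrel = Rotation.random(50, random_state=8).as_matrix()
    parent = dk.SegmentPose(Rp, np.zeros((50, 3)))
    child = dk.SegmentPose(Rp @ Rrel, np.zeros((50, 3)))
    np.testing.assert_allclose(joint_rotation(parent, child), Rrel, atol=1e-9)


def test_joint_rotation_frame_mismatch_raises():
    a = dk.SegmentPose(np.tile(np.eye(3), (2, 1, 1)), np.zeros((2, 3)))
    b = dk.SegmentPose(np.tile(np.eye(3), (3, 1, 1)), np.zeros((3, 3)))
    with pytest.raises(ValueError):
        joint_rotation(a, b)


# ------------------------------------------------------------------ Euler

def test_euler_identity_and_pure_flexion():
    ang, gim = euler_decompose(np.eye(3))
    np.testing.assert_allclose(ang, [0, 0, 0], atol=1e-12)
    assert not gim
    R30 = Rotation.from_euler("y", 30, degrees=True).as_matrix()
    ang, _ = euler_decompose(R30)
    np.testing.assert_allclose(ang, [30, 0, 0], atol=1e-10)


def test_euler_round_trip_spec_triple():
    R = euler_compose(20.0, 10.0, -15.0)
    ang, _ = euler_decompose(R)
    np.testing.assert_allclose(ang, [20, 10, -15], atol=1e-8)


@settings(max_examples=60, derandomize=True)
@given(st.floats(-170, 170), st.floats(-80, 80), st.floats(-170, 170))
def test_euler_round_trip_property(flex, lat, ax):
    """decompose(compose(angles)) is the identity away from gimbal lock."""
    ang, _ = euler_decompose(euler_compose(flex, lat, ax))
    np.testing.assert_allclose(ang, [flex, lat, ax], atol=1e-8)


def test_recomposition_reproduces_input(rng):
    R = Rotation.random(20, random_state=5).as_matrix()
    ang, _ = euler_decompose(R)
    back = euler_compose(ang[:, 0], ang[:, 1], ang[:, 2])
    np.testing.assert_allclose(back, R, atol=1e-8)


def test_gimbal_proximity_flagged():
    R = euler_compose(10.0, 89.8, 5.0)
    with pytest.warns(GimbalWarning):
        _, gim = euler_decompose(R)
    assert gim


def test_non_orthonormal_input_rejected():
    with pytest.raises(ValueError):
        euler_decompose(np.eye(3) * 1.01)


# ------------------------------------------------- marker -> joint angles

def _hip_reach_markers(model, excursion_deg, n=120, noise=0.0, seed=0):
    """Joint program flexing only the hip by ``excursion_deg``."""
    from dodgekin.synthetic import minimum_jerk
    mj, _ = minimum_jerk((n - 1) / 100.0, 100.0)
    alpha = np.tile(model.standing_posture, (n, 1))
    alpha[:, 2] += mj * excursion_deg
    markers = model.marker_positions(alpha)
    if noise > 0:
        markers += np.random.default_rng(seed).normal(0, noise, markers.shape)
    return dk.TrajectorySet(list(model.marker_names), markers, 100.0), alpha


def test_static_pose_gives_constant_angles(model):
    alpha = np.tile(model.standing_posture, (60, 1))
    ts = dk.TrajectorySet(list(model.marker_names),
                          model.marker_positions(alpha), 100.0)
    series = dk.compute_joint_angles(ts, model.clusters, model.chain)
    assert {s.joint_name for s in series} == set(dk.JOINT_ORDER)
    for s in series:
        assert np.ptp(s.flexion_extension) < 1e-9


def test_programmed_hip_excursion_recovered_noiseless(model):
    ts, _ = _hip_reach_markers(model, 30.0)
    series = {s.joint_name: s
              for s in dk.compute_joint_angles(ts, model.clusters, model.chain)}
    hip = series["hip"].flexion_extension
    assert abs((hip[-1] - hip[0]) - 30.0) < 0.1
    for j in ("ankle", "knee", "spine", "shoulder", "elbow"):
        f = series[j].flexion_extension
        assert abs(f[-1] - f[0]) < 0.1


def test_programmed_hip_excursion_recovered_with_noise(model):
    ts, _ = _hip_reach_markers(model, 30.0, noise=0.001, seed=11)
    series = {s.joint_name: s
              for s in dk.compute_joint_angles(ts, model.clusters, model.chain)}
    hip = series["hip"].flexion_extension
    assert abs((hip[-1] - hip[0]) - 30.0) < 2.0


def test_missing_cluster_names_segment(model):
    chain = model.chain
    with pytest.raises(KeyError, match="thigh"):
        clusters = [c for c in model.clusters if c.segment_name != "thigh"]
        alpha = np.tile(model.standing_posture, (5, 1))
        ts = dk.TrajectorySet(list(model.marker_names),
                              model.marker_positions(alpha), 100.0)
        dk.compute_joint_angles(ts, clusters, chain)


def test_all_returned_rotations_proper(model, rng):
    alpha = np.tile(model.standing_posture, (30, 1))
    markers = model.marker_positions(alpha)
    markers += rng.normal(0, 0.002, markers.shape)
    ts = dk.TrajectorySet(list(model.marker_names), markers, 100.0)
    for c in model.clusters:
        pose = dk.fit_rigid_pose(c, ts.markers(c.marker_names))
        R = pose.rotations[pose.valid]
        assert np.abs(R @ np.swapaxes(R, 1, 2) - np.eye(3)).max() < 1e-8
        assert np.all(np.linalg.det(R) > 0)
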