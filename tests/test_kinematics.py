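"""Forward-kinematics oracle checks and PV definitions."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from comvar.body import BodyModel, SegmentSpec, SolidSpec
from comvar.errors import ConfigurationError
from comvar.kinematics import (
    LabAnchors,
    forward_segment_coms,
    pv_channels,
    pv_foot,
    pv_foot_vectors,
    pv_lab,
    pv_lab_vectors,
    whole_body_com,
)


def brute_force_segment_coms(q, model):
    """Independent chain evaluation via scipy Rotation objects."""
    R = {}
    P = {}
    coms = np.empty((model.n_segments, 3))
    for i, seg in enumerate(model.segments):
        s, c = int(model.dof_start[i]), int(model.dof_count[i])
        angles = np.zeros(3)
        angles[:c] = q[s : s + c]
        local = Rotation.from_euler("ZXY", angles)
        parent = int(model.parent_index[i])
        if parent < 0:
            R[i] = local
            P[i] = np.zeros(3)
        else:
            R[i] = R[parent] * local
            P[i] = P[parent] + R[parent].apply(model.attach[i])
        coms[i] = P[i] + R[i].apply(model.axes[i] * model.com_offsets[i])
    return coms


def brute_force_com(q, model):
    w = model.volumes / model.volumes.sum()
    return w @ brute_force_segment_coms(q, model)


def test_chain_matches_brute_force_oracle(model, rng):
    Q = rng.uniform(-0.5, 0.5, (300, 50))
    fast = forward_segment_coms(Q, model)
    com = whole_body_com(Q, model)
    for i in range(0, 300, 7):
        expected = brute_force_segment_coms(Q[i], model)
        np.testing.assert_allclose(fast[i], expected, atol=1e-10)
    expected_com = np.array([brute_force_com(q, model) for q in Q])
    np.testing.assert_allclose(com, expected_com, atol=1e-10)


def test_kernel_and_numpy_paths_agree(model, rng):
    Q = rng.uniform(-0.6, 0.6, (500, 50))
    via_kernel = whole_body_com(Q, model)  # batch >= 64 dispatches to the kernel
    via_numpy = np.einsum("nij,i->nj", forward_segment_coms(Q, model), model.weights())
    np.testing.assert_allclose(via_kernel, via_numpy, atol=1e-12)


def test_neutral_pose_is_mid_sagittal(model):
    coms = forward_segment_coms(np.zeros(50), model)
    idx = model.segment_index
    for name in ("pelvis", "abdomen", "thorax", "neck", "head"):
        assert coms[idx[name], 1] == pytest.approx(0.0, abs=1e-15)
    for left, right in [("thigh_left", "thigh_right"), ("hand_left", "hand_right")]:
        np.testing.assert_allclose(
            coms[idx[left]] * [1, -1, 1], coms[idx[right]], atol=1e-15
        )
    assert whole_body_com(np.zeros(50), model)[1] == pytest.approx(0.0, abs=1e-15)


def test_neutral_pose_matches_hand_derived_geometry(model, profile):
    """Neutral-pose CoM from independent arithmetic on the raw measures."""
    p = profile.measures
    pi = math.pi

    def frustum(c1, c2, h):
        r1, r2 = c1 / (2 * pi), c2 / (2 * pi)
        v = pi * h * (r1**2 + r1 * r2 + r2**2) / 3
        zbar = h * (r1**2 + 2 * r1 * r2 + 3 * r2**2) / (4 * (r1**2 + r1 * r2 + r2**2))
        return v, zbar

    entries = []  # (volume, x, y, z) per segment, both sides folded in

    def add(v, x, y, z, mirrored=False):
        entries.append((v, x, y, z))
        if mirrored:
            entries.append((v, x, -y, z))

    add(pi * p["pelvis_breadth"] / 2 * p["pelvis_depth"] / 2 * p["pelvis_length"],
        0, 0, -p["pelvis_length"] / 2)
    add(pi * p["abdomen_breadth"] / 2 * p["abdomen_depth"] / 2 * p["abdomen_length"],
        0, 0, p["abdomen_length"] / 2)
    z_sh = p["abdomen_length"] + p["thorax_length"]
    add(pi * p["thorax_breadth"] / 2 * p["thorax_depth"] / 2 * p["thorax_length"],
        0, 0, p["abdomen_length"] + p["thorax_length"] / 2)
    r_neck = p["neck_circumference"] / (2 * pi)
    add(pi * r_neck**2 * p["neck_length"], 0, 0, z_sh + p["neck_length"] / 2)
    add(4 / 3 * pi * p["head_length"] / 2 * p["head_breadth"] / 2 * p["head_depth"] / 2,
        0, 0, z_sh + p["neck_length"] + p["head_length"] / 2)
    v, zb = frustum(p["upper_arm_proximal_circumference"],
                    p["upper_arm_distal_circumference"], p["upper_arm_length"])
    add(v, 0, p["shoulder_breadth"] / 2, z_sh - zb, mirrored=True)
    v, zb = frustum(p["forearm_proximal_circumference"],
                    p["forearm_distal_circumference"], p["forearm_length"])
    add(v, 0, p["shoulder_breadth"] / 2, z_sh - p["upper_arm_length"] - zb, mirrored=True)
    r_hand = p["hand_circumference"] / (2 * pi)
    add(4 / 3 * pi * r_hand**3, 0, p["shoulder_breadth"] / 2,
        z_sh - p["upper_arm_length"] - p["forearm_length"] - r_hand, mirrored=True)
    z_hip = -p["pelvis_length"]
    v, zb = frustum(p["thigh_proximal_circumference"],
                    p["thigh_distal_circumference"], p["thigh_length"])
    add(v, 0, p["hip_breadth"] / 2, z_hip - zb, mirrored=True)
    v, zb = frustum(p["shank_proximal_circumference"],
                    p["shank_distal_circumference"], p["shank_length"])
    add(v, 0, p["hip_breadth"] / 2, z_hip - p["thigh_length"] - zb, mirrored=True)
    v, zb = frustum(p["foot_proximal_circumference"],
                    p["foot_distal_circumference"], p["foot_length"])
    add(v, zb, p["hip_breadth"] / 2, z_hip - p["thigh_length"] - p["shank_length"],
        mirrored=True)

    arr = np.array(entries)
    expected = (arr[:, 0:1] * arr[:, 1:]).sum(axis=0) / arr[:, 0].sum()
    np.testing.assert_allclose(whole_body_com(np.zeros(50), model), expected, atol=1e-12)
    assert pv_lab(np.zeros(50), model).norm == pytest.approx(np.linalg.norm(expected))


def mirror_configuration(q, model):
    """Reflect a configuration about the sagittal plane (y -> -y)."""
    out = np.empty_like(q)
    idx = model.segment_index
    swap = {name: name for name in idx}
    for left in [n for n in idx if n.endswith("_left")]:
        right = left.replace("_left", "_right")
        swap[left], swap[right] = right, left
    for name, i in idx.items():
        j = idx[swap[name]]
        s_i, c_i = int(model.dof_start[i]), int(model.dof_count[i])
        s_j = int(model.dof_start[j])
        angles = q[s_j : s_j + c_i].copy()
        angles[0] = -angles[0]  # Z flips under reflection
        angles[1] = -angles[1]  # X flips
        out[s_i : s_i + c_i] = angles  # Y preserved
    return out


def test_mirrored_pose_swaps_y_coordinates(model, rng):
    q = rng.uniform(-0.4, 0.4, 50)
    coms = forward_segment_coms(q, model)
    coms_m = forward_segment_coms(mirror_configuration(q, model), model)
    idx = model.segment_index
    for name, i in idx.items():
        partner = name.replace("_left", "_right") if name.endswith("_left") else (
            name.replace("_right", "_left") if name.endswith("_right") else name)
        j = idx[partner]
        np.testing.assert_allclose(coms_m[j], coms[i] * [1, -1, 1], atol=1e-12)


def test_single_segment_model_com_is_segment_com(rng):
    solid = SolidSpec("conical_frustum", {"r_proximal": 0.05, "r_distal": 0.03, "height": 0.4})
    seg = SegmentSpec("only", solid, None, (0.0, 0.0, 0.0), (0.0, 0.0, -1.0))
    from comvar.body import solid_com_offset, solid_volume

    model = BodyModel(
        segments=[seg],
        volumes=np.array([solid_volume(solid)]),
        com_offsets=np.array([solid_com_offset(solid)]),
    )
    q = rng.uniform(-1, 1, 3)
    np.testing.assert_allclose(
        whole_body_com(q, model), forward_segment_coms(q, model)[0], atol=1e-15
    )


def test_rigid_root_rotation_preserves_norm(model, rng):
    q = rng.uniform(-0.4, 0.4, 50)
    extra = Rotation.from_rotvec(rng.uniform(-1, 1, 3))
    q2 = q.copy()
    q2[:3] = (extra * Rotation.from_euler("ZXY", q[:3])).as_euler("ZXY")
    com1 = whole_body_com(q, model)
    com2 = whole_body_com(q2, model)
    assert np.linalg.norm(com1) == pytest.approx(np.linalg.norm(com2), abs=1e-10)
    np.testing.assert_allclose(extra.apply(com1), com2, atol=1e-10)


def test_pv_foot_minus_pv_lab_is_anchor_difference(model, rng):
    q = rng.uniform(-0.4, 0.4, (40, 50))
    anchors = LabAnchors(r_pelvis=rng.normal(0, 1, (40, 3)), r_rfoot=rng.normal(0, 1, (40, 3)))
    diff = pv_foot_vectors(q, anchors, model) - pv_lab_vectors(q, model)
    np.testing.assert_allclose(diff, anchors.r_pelvis - anchors.r_rfoot, atol=0)


def test_pv_foot_reduces_to_pv_lab_with_equal_anchors(model, rng):
    q = rng.uniform(-0.3, 0.3, 50)
    r = rng.normal(0, 1, 3)
    anchors = LabAnchors(r_pelvis=r, r_rfoot=r.copy())
    np.testing.assert_allclose(pv_foot(q, anchors, model).v, pv_lab(q, model).v, atol=0)


def test_pv_vector_invariants(model, rng):
    for _ in range(10):
        vec = pv_lab(rng.uniform(-0.5, 0.5, 50), model)
        assert vec.norm == pytest.approx(np.linalg.norm(vec.v))
        assert all(vec.norm >= al - 1e-15 for al in vec.axis_lengths)
    channels = pv_channels(rng.normal(0, 1, (5, 3)))
    assert channels.shape == (5, 4)
    assert np.all(channels[:, 0] + 1e-12 >= channels[:, 1:].max(axis=1))


def test_dimension_mismatch_raises(model):
    with pytest.raises(ConfigurationError):
        whole_body_com(np.zeros(49), model)
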