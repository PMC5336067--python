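import numpy as np
import pytest

from amplimotion.core_model import (
    CHILDREN,
    JOINT_INDEX,
    JOINTS,
    JointName,
    MotionTrace,
    PARENT,
    default_rest_pose,
)
from amplimotion.motion_io import (
    BvhError,
    ProfileSchemaError,
    StreamFormatError,
    load_profile,
    read_bvh,
    read_joint_stream,
    save_profile,
    write_bvh,
    write_joint_stream,
)


def _small_trace(n=6):
    pos = np.tile(default_rest_pose().as_array(), (n, 1, 1))
    pos += np.linspace(0, 0.01, n)[:, None, None]
    return MotionTrace(np.arange(n) / 30.0, pos)


@pytest.mark.parametrize("ext", ["csv", "jsonl"])
def test_stream_roundtrip_lossless(tmp_path, ext):
    trace = _small_trace()
    path = tmp_path / f"t.{ext}"
    write_joint_stream(trace, path)
    back = read_joint_stream(path)
    np.testing.assert_array_equal(back.positions, trace.positions)
    np.testing.assert_array_equal(back.times, trace.times)


def test_stream_rejects_bad_header(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("time,joint,a,b,c\n0,head,0,0,0\n")
    with pytest.raises(StreamFormatError):
        read_joint_stream(p)


def test_stream_names_unknown_joint(tmp_path):
    p = tmp_path / "bad.csv"
    rows = ["time,joint,x,y,z"]
    for j in JOINTS:
        rows.append(f"0,{j.value},0,0,1")
    rows[3] = "0,flipper_left,0,0,1"
    p.write_text("\n".join(rows) + "\n")
    with pytest.raises(StreamFormatError, match="flipper_left"):
        read_joint_stream(p)


def test_stream_names_missing_joint(tmp_path):
    p = tmp_path / "bad.csv"
    rows = ["time,joint,x,y,z"]
    for j in JOINTS:
        if j is not JointName.HEAD:
            rows.append(f"0,{j.value},0,0,1")
    p.write_text("\n".join(rows) + "\n")
    with pytest.raises(StreamFormatError, match="head"):
        read_joint_stream(p)


def test_stream_rejects_nonincreasing_time(tmp_path):
    p = tmp_path / "t.csv"
    rows = ["time,joint,x,y,z"]
    for t in (0.0, 1.0 / 30.0, 0.02):  # third frame goes backwards
        for j in JOINTS:
            rows.append(f"{t},{j.value},0,0,1")
    p.write_text("\n".join(rows) + "\n")
    with pytest.raises(StreamFormatError, match="increasing"):
        read_joint_stream(p)


def test_stream_rejects_duplicate_rows(tmp_path):
    trace = _small_trace()
    p = tmp_path / "t.csv"
    write_joint_stream(trace, p)
    lines = p.read_text().splitlines()
    p.write_text("\n".join(lines + [lines[1]]) + "\n")
    with pytest.raises(StreamFormatError, match="duplicate"):
        read_joint_stream(p)


# ---------------------------------------------------------------------------
# BVH
# ---------------------------------------------------------------------------

def test_bvh_roundtrip_positions(tmp_path, avatar):
    trace = _small_trace()
    p = tmp_path / "t.bvh"
    write_bvh(avatar, trace, p)
    model, back = read_bvh(p)
    np.testing.assert_allclose(back.positions, trace.positions, atol=1e-8)
    for (parent, child), ln in model.bone_lengths.items():
        assert ln == pytest.approx(avatar.length(parent, child), abs=1e-6)


def _rotation_bvh_text(angle_deg: float) -> str:
    """Canonical hierarchy; zero rotations everywhere except a root
    Z-rotation, so FK must rigidly rotate the rest pose about the root."""
    rest = default_rest_pose()
    lines = ["HIERARCHY"]
    channel_count = [0]

    def emit(j, depth):
        ind = "  " * depth
        kw = "ROOT" if PARENT[j] is None else "JOINT"
        off = rest[j] - (rest[PARENT[j]] if PARENT[j] is not None else 0.0)
        lines.append(f"{ind}{kw} {j.value}")
        lines.append(ind + "{")
        lines.append(f"{ind}  OFFSET {off[0]} {off[1]} {off[2]}")
        if PARENT[j] is None:
            lines.append(f"{ind}  CHANNELS 6 Xposition Yposition Zposition "
                         "Zrotation Xrotation Yrotation")
            channel_count[0] += 6
        else:
            lines.append(f"{ind}  CHANNELS 3 Zrotation Xrotation Yrotation")
            channel_count[0] += 3
        if CHILDREN[j]:
            for c in CHILDREN[j]:
                emit(c, depth + 1)
        else:
            lines.append(f"{ind}  End Site")
            lines.append(ind + "  {")
            lines.append(f"{ind}    OFFSET 0 0 0")
            lines.append(ind + "  }")
        lines.append(ind + "}")

    emit(JointName.HIP_CENTER, 0)
    row = ["0"] * channel_count[0]
    row[3] = str(angle_deg)  # root Zrotation
    lines += ["MOTION", "Frames: 1", "Frame Time: 0.033333333",
              " ".join(row)]
    return "\n".join(lines)


def test_bvh_rotation_channels_forward_kinematics(tmp_path):
    angle = 90.0
    p = tmp_path / "rot.bvh"
    p.write_text(_rotation_bvh_text(angle))
    _, trace = read_bvh(p)
    rest = default_rest_pose().as_array()
    root = rest[JOINT_INDEX[JointName.HIP_CENTER]]
    a = np.deg2rad(angle)
    rz = np.array([[np.cos(a), -np.sin(a), 0],
                   [np.sin(a), np.cos(a), 0],
                   [0, 0, 1]])
    expected = (rest - root) @ rz.T + root
    np.testing.assert_allclose(trace.positions[0], expected, atol=1e-9)


def test_bvh_unknown_joint_name_raises(tmp_path):
    text = _rotation_bvh_text(0.0).replace("JOINT hand_left", "JOINT tentacle")
    p = tmp_path / "bad.bvh"
    p.write_text(text)
    with pytest.raises(BvhError, match="tentacle"):
        read_bvh(p)


def test_bvh_truncated_raises(tmp_path):
    p = tmp_path / "trunc.bvh"
    p.write_text(_rotation_bvh_text(0.0)[:200])
    with pytest.raises(BvhError):
        read_bvh(p)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def test_profile_roundtrip(tmp_path, profile):
    p = tmp_path / "prof.json"
    save_profile(profile, p)
    back = load_profile(p)
    np.testing.assert_array_equal(back.body_offset, profile.body_offset)
    for limb, lc in profile.limbs.items():
        lc2 = back.limbs[limb]
        np.testing.assert_array_equal(lc2.resting, lc.resting)
        np.testing.assert_array_equal(lc2.factors_pos, lc.factors_pos)
        np.testing.assert_array_equal(lc2.factors_neg, lc.factors_neg)
        np.testing.assert_array_equal(lc2.offset, lc.offset)


def test_profile_version_mismatch(tmp_path, profile):
    import json
    p = tmp_path / "prof.json"
    save_profile(profile, p)
    doc = json.loads(p.read_text())
    doc["version"] = "999"
    p.write_text(json.dumps(doc))
    with pytest.raises(ProfileSchemaError):
        load_profile(p)
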