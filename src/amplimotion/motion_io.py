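"""Readers and writers for motion traces, BVH files and calibration profiles.

Joint streams are long-format records ``time, joint, x, y, z`` (SI seconds
and metres) in CSV or JSONL; the two dialects parse to identical traces.
BVH serves as the standard skeletal-motion interchange format; files are
interpreted in this package's z-up frame (documented, rather than the y-up
convention some tools assume).  All readers reject malformed input instead
of silently repairing it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationProfile, LimbCalibration, PROFILE_VERSION
from .core_model import (
    CHILDREN,
    JOINT_INDEX,
    JOINTS,
    JointName,
    MotionTrace,
    PARENT,
    SkeletonModel,
    SkeletonPose,
    default_rest_pose,
    forward_place,
)

__all__ = [
    "StreamFormatError",
    "BvhError",
    "ProfileSchemaError",
    "read_joint_stream",
    "write_joint_stream",
    "read_bvh",
    "write_bvh",
    "save_profile",
    "load_profile",
    "BVH_NAME_MAP",
]


class StreamFormatError(ValueError):
    """Malformed joint-stream file."""


class BvhError(ValueError):
    """Malformed or unmappable BVH file."""


class ProfileSchemaError(ValueError):
    """Calibration profile JSON does not match the expected schema/version."""


# ---------------------------------------------------------------------------
# Joint streams (CSV / JSONL)
# ---------------------------------------------------------------------------

_STREAM_COLUMNS = ["time", "joint", "x", "y", "z"]
_VALID_JOINTS = {j.value for j in JOINTS}


def read_joint_stream(path: str | Path, dialect: str | None = None,
                      frame_rate: float | None = None) -> MotionTrace:
    """Parse a long-format joint stream into a :class:`MotionTrace`.

    ``dialect`` is ``"csv"`` or ``"jsonl"``; inferred from the suffix when
    omitted.  Every frame must contain all 20 joints exactly once, times must
    be non-negative and strictly increasing across frames.
    """
    path = Path(path)
    if dialect is None:
        dialect = "jsonl" if path.suffix.lower() in (".jsonl", ".ndjson") else "csv"
    if dialect == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
    elif dialect == "jsonl":
        df = pd.read_json(path, lines=True, precise_float=True)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if list(df.columns) != _STREAM_COLUMNS:
        raise StreamFormatError(
            f"{path}: header must be {_STREAM_COLUMNS}, got {list(df.columns)}"
        )
    bad = df.loc[~df["joint"].isin(_VALID_JOINTS)]
    if not bad.empty:
        row = bad.index[0]
        raise StreamFormatError(
            f"{path}: unknown joint {bad.iloc[0]['joint']!r} at row {row}"
        )
    if (df["time"] < 0).any():
        raise StreamFormatError(f"{path}: negative timestamps")
    for col in ("time", "x", "y", "z"):
        if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
            raise StreamFormatError(f"{path}: non-finite value in column {col!r}")

    dup = df.duplicated(subset=["time", "joint"])
    if dup.any():
        row = int(df.index[dup][0])
        raise StreamFormatError(
            f"{path}: duplicate (time, joint) entry at row {row}"
        )
    times = df["time"].unique()
    if not np.all(np.diff(times) > 0):
        raise StreamFormatError(f"{path}: frame times not strictly increasing")

    n = len(times)
    positions = np.full((n, len(JOINTS), 3), np.nan)
    frame_of = {t: i for i, t in enumerate(times)}
    ti = df["time"].map(frame_of).to_numpy()
    ji = df["joint"].map({j.value: i for i, j in enumerate(JOINTS)}).to_numpy()
    positions[ti, ji] = df[["x", "y", "z"]].to_numpy(dtype=float)

    missing = np.argwhere(np.isnan(positions[:, :, 0]))
    if missing.size:
        f, j = missing[0]
        raise StreamFormatError(
            f"{path}: frame {f} (t={times[f]}) missing joint {JOINTS[j].value!r}"
        )
    if frame_rate is None:
        frame_rate = 1.0 / float(np.median(np.diff(times))) if n > 1 else 30.0
    return MotionTrace(times.astype(float), positions, frame_rate=frame_rate)


def write_joint_stream(trace: MotionTrace, path: str | Path,
                       dialect: str | None = None) -> None:
    """Write a trace as CSV or JSONL (17 significant digits: lossless round trip)."""
    path = Path(path)
    if dialect is None:
        dialect = "jsonl" if path.suffix.lower() in (".jsonl", ".ndjson") else "csv"
    with open(path, "w") as fh:
        if dialect == "csv":
            fh.write(",".join(_STREAM_COLUMNS) + "\n")
            for i in range(len(trace)):
                t = trace.times[i]
                for k, j in enumerate(JOINTS):
                    x, y, z = trace.positions[i, k]
                    fh.write(f"{t:.17g},{j.value},{x:.17g},{y:.17g},{z:.17g}\n")
        elif dialect == "jsonl":
            for i in range(len(trace)):
                t = trace.times[i]
                for k, j in enumerate(JOINTS):
                    x, y, z = trace.positions[i, k]
                    fh.write(json.dumps(
                        {"time": t, "joint": j.value, "x": x, "y": y, "z": z}
                    ) + "\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# BVH
# ---------------------------------------------------------------------------

# Common BVH joint names mapped onto the canonical set (case-insensitive);
# canonical names always map to themselves.
BVH_NAME_MAP: dict[str, JointName] = {
    "hips": JointName.HIP_CENTER,
    "spine": JointName.SPINE,
    "chest": JointName.SHOULDER_CENTER,
    "neck": JointName.SHOULDER_CENTER,
    "head": JointName.HEAD,
    "leftshoulder": JointName.SHOULDER_LEFT,
    "leftarm": JointName.SHOULDER_LEFT,
    "leftelbow": JointName.ELBOW_LEFT,
    "leftforearm": JointName.ELBOW_LEFT,
    "leftwrist": JointName.WRIST_LEFT,
    "lefthand": JointName.HAND_LEFT,
    "rightshoulder": JointName.SHOULDER_RIGHT,
    "rightarm": JointName.SHOULDER_RIGHT,
    "rightelbow": JointName.ELBOW_RIGHT,
    "rightforearm": JointName.ELBOW_RIGHT,
    "rightwrist": JointName.WRIST_RIGHT,
    "righthand": JointName.HAND_RIGHT,
    "leftupleg": JointName.HIP_LEFT,
    "lefthip": JointName.HIP_LEFT,
    "leftknee": JointName.KNEE_LEFT,
    "leftleg": JointName.KNEE_LEFT,
    "leftankle": JointName.ANKLE_LEFT,
    "leftfoot": JointName.FOOT_LEFT,
    "rightupleg": JointName.HIP_RIGHT,
    "righthip": JointName.HIP_RIGHT,
    "rightknee": JointName.KNEE_RIGHT,
    "rightleg": JointName.KNEE_RIGHT,
    "rightankle": JointName.ANKLE_RIGHT,
    "rightfoot": JointName.FOOT_RIGHT,
}
BVH_NAME_MAP.update({j.value: j for j in JOINTS})


class _BvhJoint:
    def __init__(self, name: str, parent: "_BvhJoint | None") -> None:
        self.name = name
        self.parent = parent
        self.offset = np.zeros(3)
        self.channels: list[str] = []
        self.children: list["_BvhJoint"] = []


def _parse_bvh(text: str) -> tuple[list[_BvhJoint], np.ndarray, float]:
    tokens = text.replace("{", " { ").replace("}", " } ").split()
    pos = 0

    def next_tok() -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise BvhError("unexpected end of file")
        tok = tokens[pos]
        pos += 1
        return tok

    if next_tok().upper() != "HIERARCHY":
        raise BvhError("missing HIERARCHY section")

    joints: list[_BvhJoint] = []

    def parse_joint(parent: _BvhJoint | None) -> None:
        nonlocal pos
        kw = next_tok().upper()
        if kw not in ("ROOT", "JOINT", "END"):
            raise BvhError(f"unexpected token {kw!r} in hierarchy")
        name = next_tok()
        if kw == "END":  # "End Site"
            name = None
        if next_tok() != "{":
            raise BvhError("expected '{'")
        joint = _BvhJoint(name, parent) if name is not None else None
        if joint is not None:
            joints.append(joint)
            if parent is not None:
                parent.children.append(joint)
        while True:
            tok = next_tok()
            up = tok.upper()
            if up == "OFFSET":
                off = np.array([float(next_tok()) for _ in range(3)])
                if joint is not None:
                    joint.offset = off
            elif up == "CHANNELS":
                n = int(next_tok())
                chans = [next_tok() for _ in range(n)]
                if joint is not None:
                    joint.channels = chans
            elif up in ("JOINT", "END"):
                pos -= 1  # push the keyword back and recurse
                parse_joint(joint)
            elif tok == "}":
                return
            else:
                raise BvhError(f"unexpected token {tok!r} in joint block")

    parse_joint(None)

    if next_tok().upper() != "MOTION":
        raise BvhError("missing MOTION section")
    if next_tok().lower() != "frames:":
        raise BvhError("missing 'Frames:'")
    n_frames = int(next_tok())
    t1, t2 = next_tok().lower(), next_tok().lower()
    if (t1, t2) != ("frame", "time:"):
        raise BvhError("missing 'Frame Time:'")
    frame_time = float(next_tok())
    n_channels = sum(len(j.channels) for j in joints)
    values = np.array([float(next_tok()) for _ in range(n_frames * n_channels)])
    return joints, values.reshape(n_frames, n_channels), frame_time


_ROT = {
    "x": lambda a: np.array([[1, 0, 0],
                             [0, np.cos(a), -np.sin(a)],
                             [0, np.sin(a), np.cos(a)]]),
    "y": lambda a: np.array([[np.cos(a), 0, np.sin(a)],
                             [0, 1, 0],
                             [-np.sin(a), 0, np.cos(a)]]),
    "z": lambda a: np.array([[np.cos(a), -np.sin(a), 0],
                             [np.sin(a), np.cos(a), 0],
                             [0, 0, 1]]),
}


def read_bvh(path: str | Path,
             name_map: dict[str, JointName] | None = None
             ) -> tuple[SkeletonModel, MotionTrace]:
    """Read a BVH file covering the 20 canonical joints.

    Joint positions are computed by forward kinematics from offsets and
    channel values (rotations in degrees, applied in channel order).  Joint
    names are resolved case-insensitively through ``name_map`` (default:
    :data:`BVH_NAME_MAP`); names that cannot be mapped raise
    :class:`BvhError` listing the offenders.
    """
    name_map = BVH_NAME_MAP if name_map is None else name_map
    lowered = {k.lower(): v for k, v in name_map.items()}
    joints, frames, frame_time = _parse_bvh(Path(path).read_text())

    unmapped = [j.name for j in joints if j.name.lower() not in lowered]
    if unmapped:
        raise BvhError(f"BVH joints not mappable to the canonical set: {unmapped}")
    canon = [lowered[j.name.lower()] for j in joints]
    if set(canon) != set(JOINTS):
        missing = sorted(j.value for j in set(JOINTS) - set(canon))
        raise BvhError(f"BVH hierarchy does not cover all 20 joints; missing {missing}")

    # Channel slices per joint.
    slices = []
    start = 0
    for j in joints:
        slices.append(slice(start, start + len(j.channels)))
        start += len(j.channels)

    n_frames = frames.shape[0]
    positions = np.zeros((n_frames, len(JOINTS), 3))
    order = {id(j): i for i, j in enumerate(joints)}

    for f in range(n_frames):
        glob_pos: dict[int, np.ndarray] = {}
        glob_rot: dict[int, np.ndarray] = {}
        for j, sl, cj in zip(joints, slices, canon):
            vals = frames[f, sl]
            trans = np.zeros(3)
            rot = np.eye(3)
            for ch, v in zip(j.channels, vals):
                chl = ch.lower()
                if chl.endswith("position"):
                    trans["xyz".index(chl[0])] += v
                elif chl.endswith("rotation"):
                    rot = rot @ _ROT[chl[0]](np.deg2rad(v))
                else:
                    raise BvhError(f"unknown channel {ch!r}")
            local = j.offset + trans
            if j.parent is None:
                p, r = local, rot
            else:
                pi = order[id(j.parent)]
                p = glob_pos[pi] + glob_rot[pi] @ local
                r = glob_rot[pi] @ rot
            i = order[id(j)]
            glob_pos[i], glob_rot[i] = p, r
            positions[f, JOINT_INDEX[cj]] = p

    times = np.arange(n_frames) * frame_time
    trace = MotionTrace(times, positions, frame_rate=1.0 / frame_time)

    lengths = {}
    by_canon = {c: j for j, c in zip(joints, canon)}
    for child, parent in PARENT.items():
        if parent is None:
            continue
        ln = float(np.linalg.norm(by_canon[child].offset))
        if ln <= 0:
            # Fall back to first-frame distance for zero offsets.
            ln = float(np.linalg.norm(
                positions[0, JOINT_INDEX[child]] - positions[0, JOINT_INDEX[parent]]))
        if ln <= 0:
            raise BvhError(f"zero-length bone {parent.value}->{child.value}")
        lengths[(parent, child)] = ln
    return SkeletonModel(lengths), trace


def write_bvh(model: SkeletonModel, trace: MotionTrace, path: str | Path) -> None:
    """Write a trace as BVH with translation channels on every joint.

    Offsets encode the model's rest geometry; per-frame translation channels
    carry the residual of each joint's parent-relative position, so that a
    write→read round trip reproduces positions exactly (up to text
    precision).  Rotation channels are deliberately not emitted.
    """
    rest = forward_place(model, default_rest_pose())
    lines: list[str] = ["HIERARCHY"]

    def emit(joint: JointName, depth: int) -> None:
        indent = "  " * depth
        kw = "ROOT" if PARENT[joint] is None else "JOINT"
        lines.append(f"{indent}{kw} {joint.value}")
        lines.append(f"{indent}{{")
        parent = PARENT[joint]
        off = rest[joint] - (rest[parent] if parent is not None else 0.0)
        lines.append(f"{indent}  OFFSET {off[0]:.10g} {off[1]:.10g} {off[2]:.10g}")
        lines.append(f"{indent}  CHANNELS 3 Xposition Yposition Zposition")
        kids = CHILDREN[joint]
        if kids:
            for c in kids:
                emit(c, depth + 1)
        else:
            lines.append(f"{indent}  End Site")
            lines.append(f"{indent}  {{")
            lines.append(f"{indent}    OFFSET 0 0 0")
            lines.append(f"{indent}  }}")
        lines.append(f"{indent}}}")

    emit(JointName.HIP_CENTER, 0)
    lines.append("MOTION")
    lines.append(f"Frames: {len(trace)}")
    lines.append(f"Frame Time: {1.0 / trace.frame_rate:.10g}")

    # Depth-first channel order must match the hierarchy emission order.
    dfs_order: list[JointName] = []

    def walk(j: JointName) -> None:
        dfs_order.append(j)
        for c in CHILDREN[j]:
            walk(c)

    walk(JointName.HIP_CENTER)

    for i in range(len(trace)):
        vals: list[float] = []
        for j in dfs_order:
            parent = PARENT[j]
            off = rest[j] - (rest[parent] if parent is not None else 0.0)
            pos = trace.positions[i, JOINT_INDEX[j]]
            base = trace.positions[i, JOINT_INDEX[parent]] if parent is not None else 0.0
            t = pos - base - off
            vals.extend(t)
        lines.append(" ".join(f"{v:.10g}" for v in vals))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Calibration profiles (JSON)
# ---------------------------------------------------------------------------

_LIMB_KEYS = {"resting", "range_pos", "range_neg", "factors", "offset"}


def save_profile(profile: CalibrationProfile, path: str | Path) -> None:
    doc = {
        "version": profile.version,
        "body_offset": list(profile.body_offset),
        "limbs": {
            limb: {
                "resting": list(lc.resting),
                "range_pos": list(lc.range_pos),
                "range_neg": list(lc.range_neg),
                "factors": {"pos": list(lc.factors_pos), "neg": list(lc.factors_neg)},
                "offset": list(lc.offset),
                "unusable": {"pos": [bool(v) for v in lc.unusable_pos],
                             "neg": [bool(v) for v in lc.unusable_neg]},
            }
            for limb, lc in profile.limbs.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_profile(path: str | Path) -> CalibrationProfile:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ProfileSchemaError(f"{path}: not valid JSON ({e})")
    version = doc.get("version")
    if version != PROFILE_VERSION:
        raise ProfileSchemaError(
            f"{path}: unsupported profile version {version!r} "
            f"(expected {PROFILE_VERSION!r})"
        )
    if "limbs" not in doc:
        raise ProfileSchemaError(f"{path}: missing 'limbs' key")
    limbs: dict[str, LimbCalibration] = {}
    for limb, entry in doc["limbs"].items():
        missing = _LIMB_KEYS - set(entry)
        if missing:
            raise ProfileSchemaError(
                f"{path}: limb {limb!r} missing keys {sorted(missing)}"
            )
        unusable = entry.get("unusable", {"pos": [False] * 3, "neg": [False] * 3})
        limbs[limb] = LimbCalibration(
            resting=entry["resting"],
            range_pos=entry["range_pos"],
            range_neg=entry["range_neg"],
            factors_pos=entry["factors"]["pos"],
            factors_neg=entry["factors"]["neg"],
            offset=entry["offset"],
            unusable_pos=unusable["pos"],
            unusable_neg=unusable["neg"],
        )
    return CalibrationProfile(limbs=limbs,
                              body_offset=doc.get("body_offset", [0.0, 0.0, 0.0]),
                              version=version)
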