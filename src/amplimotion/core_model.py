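"""Canonical 20-joint skeleton, poses, motion traces and two-bone IK.

The skeleton mirrors the joint set delivered by first-generation consumer
depth sensors (Kinect V1): a trunk chain (hip centre, spine, shoulder
centre, head) plus four five-joint limb chains.  Coordinates are metres in
a right-handed frame with

* ``z`` vertical (up),
* ``y`` lateral (to the avatar's left in the viewing plane),
* ``x`` depth (toward the sensor / forward).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "JointName",
    "PARENT",
    "CHILDREN",
    "SkeletonPose",
    "SkeletonModel",
    "MotionTrace",
    "InvalidPoseError",
    "fit_skeleton_to_pose",
    "forward_place",
    "default_rest_pose",
    "default_skeleton_model",
    "solve_two_bone_ik",
    "solve_two_bone_ik_batch",
]

DEFAULT_FRAME_RATE = 30.0  # Hz, Kinect V1 nominal
TIMESTAMP_TOLERANCE = 1e-3  # s, allowed deviation from uniform spacing


class JointName(str, Enum):
    """The 20 canonical joints, ordered trunk-first then limbs."""

    HIP_CENTER = "hip_center"
    SPINE = "spine"
    SHOULDER_CENTER = "shoulder_center"
    HEAD = "head"
    SHOULDER_LEFT = "shoulder_left"
    ELBOW_LEFT = "elbow_left"
    WRIST_LEFT = "wrist_left"
    HAND_LEFT = "hand_left"
    SHOULDER_RIGHT = "shoulder_right"
    ELBOW_RIGHT = "elbow_right"
    WRIST_RIGHT = "wrist_right"
    HAND_RIGHT = "hand_right"
    HIP_LEFT = "hip_left"
    KNEE_LEFT = "knee_left"
    ANKLE_LEFT = "ankle_left"
    FOOT_LEFT = "foot_left"
    HIP_RIGHT = "hip_right"
    KNEE_RIGHT = "knee_right"
    ANKLE_RIGHT = "ankle_right"
    FOOT_RIGHT = "foot_right"


JOINTS: tuple[JointName, ...] = tuple(JointName)
JOINT_INDEX: dict[JointName, int] = {j: i for i, j in enumerate(JOINTS)}
N_JOINTS = len(JOINTS)

# Tree rooted at the hip centre; every other joint has exactly one parent.
PARENT: dict[JointName, JointName | None] = {
    JointName.HIP_CENTER: None,
    JointName.SPINE: JointName.HIP_CENTER,
    JointName.SHOULDER_CENTER: JointName.SPINE,
    JointName.HEAD: JointName.SHOULDER_CENTER,
    JointName.SHOULDER_LEFT: JointName.SHOULDER_CENTER,
    JointName.ELBOW_LEFT: JointName.SHOULDER_LEFT,
    JointName.WRIST_LEFT: JointName.ELBOW_LEFT,
    JointName.HAND_LEFT: JointName.WRIST_LEFT,
    JointName.SHOULDER_RIGHT: JointName.SHOULDER_CENTER,
    JointName.ELBOW_RIGHT: JointName.SHOULDER_RIGHT,
    JointName.WRIST_RIGHT: JointName.ELBOW_RIGHT,
    JointName.HAND_RIGHT: JointName.WRIST_RIGHT,
    JointName.HIP_LEFT: JointName.HIP_CENTER,
    JointName.KNEE_LEFT: JointName.HIP_LEFT,
    JointName.ANKLE_LEFT: JointName.KNEE_LEFT,
    JointName.FOOT_LEFT: JointName.ANKLE_LEFT,
    JointName.HIP_RIGHT: JointName.HIP_CENTER,
    JointName.KNEE_RIGHT: JointName.HIP_RIGHT,
    JointName.ANKLE_RIGHT: JointName.KNEE_RIGHT,
    JointName.FOOT_RIGHT: JointName.ANKLE_RIGHT,
}

CHILDREN: dict[JointName, tuple[JointName, ...]] = {
    j: tuple(c for c, p in PARENT.items() if p is j) for j in JOINTS
}

TRUNK_JOINTS: tuple[JointName, ...] = (
    JointName.HIP_CENTER,
    JointName.SPINE,
    JointName.SHOULDER_CENTER,
    JointName.HEAD,
    JointName.SHOULDER_LEFT,
    JointName.SHOULDER_RIGHT,
    JointName.HIP_LEFT,
    JointName.HIP_RIGHT,
)


class InvalidPoseError(ValueError):
    """Raised when a pose violates skeleton invariants (e.g. coincident bones)."""


@dataclass
class SkeletonPose:
    """One time-stamped skeleton sample: joint positions in metres.

    ``positions`` maps every canonical joint to a length-3 float vector.
    """

    timestamp: float
    positions: dict[JointName, np.ndarray]

    def __post_init__(self) -> None:
        missing = [j for j in JOINTS if j not in self.positions]
        if missing:
            raise InvalidPoseError(f"pose missing joints: {[j.value for j in missing]}")
        for j, p in self.positions.items():
            arr = np.asarray(p, dtype=float)
            if arr.shape != (3,):
                raise InvalidPoseError(f"joint {j.value}: position must be a 3-vector")
            if not np.all(np.isfinite(arr)):
                raise InvalidPoseError(f"joint {j.value}: non-finite coordinates")
            self.positions[j] = arr

    def __getitem__(self, joint: JointName) -> np.ndarray:
        return self.positions[joint]

    def as_array(self) -> np.ndarray:
        """(20, 3) array in canonical joint order."""
        return np.stack([self.positions[j] for j in JOINTS])

    @classmethod
    def from_array(cls, timestamp: float, arr: np.ndarray) -> "SkeletonPose":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_JOINTS, 3):
            raise InvalidPoseError(f"expected ({N_JOINTS}, 3) array, got {arr.shape}")
        return cls(timestamp, {j: arr[i].copy() for i, j in enumerate(JOINTS)})


@dataclass
class SkeletonModel:
    """Bone-length model of one subject: parent map plus segment lengths."""

    bone_lengths: dict[tuple[JointName, JointName], float]
    parent: Mapping[JointName, JointName | None] = field(default_factory=lambda: dict(PARENT))

    def __post_init__(self) -> None:
        for (p, c), length in self.bone_lengths.items():
            if self.parent.get(c) is not p:
                raise ValueError(f"({p.value}, {c.value}) is not a bone of the hierarchy")
            if not length > 0:
                raise ValueError(f"bone ({p.value}, {c.value}) has non-positive length {length}")

    def length(self, parent: JointName, child: JointName) -> float:
        return self.bone_lengths[(parent, child)]

    def arm_length(self, side: str) -> float:
        """Shoulder-to-hand reach: the avatar's required range for that hand."""
        s, e, w, h = _ARM_CHAIN[side]
        return self.length(s, e) + self.length(e, w) + self.length(w, h)

    def leg_length(self, side: str) -> float:
        h, k, a, f = _LEG_CHAIN[side]
        return self.length(h, k) + self.length(k, a) + self.length(a, f)


_ARM_CHAIN = {
    "left": (JointName.SHOULDER_LEFT, JointName.ELBOW_LEFT, JointName.WRIST_LEFT, JointName.HAND_LEFT),
    "right": (JointName.SHOULDER_RIGHT, JointName.ELBOW_RIGHT, JointName.WRIST_RIGHT, JointName.HAND_RIGHT),
}
_LEG_CHAIN = {
    "left": (JointName.HIP_LEFT, JointName.KNEE_LEFT, JointName.ANKLE_LEFT, JointName.FOOT_LEFT),
    "right": (JointName.HIP_RIGHT, JointName.KNEE_RIGHT, JointName.ANKLE_RIGHT, JointName.FOOT_RIGHT),
}


class MotionTrace:
    """Ordered, uniformly sampled sequence of skeleton poses.

    Internally stored as a (T, 20, 3) float array plus a time vector, which
    keeps whole-trace operations (calibration, amplification, gadgets)
    vectorised.  Timestamps must be strictly increasing and uniform within
    1 ms of the nominal frame interval.
    """

    def __init__(self, times: np.ndarray, positions: np.ndarray,
                 frame_rate: float = DEFAULT_FRAME_RATE) -> None:
        times = np.asarray(times, dtype=float)
        positions = np.asarray(positions, dtype=float)
        if positions.ndim != 3 or positions.shape[1:] != (N_JOINTS, 3):
            raise ValueError(f"positions must be (T, {N_JOINTS}, 3); got {positions.shape}")
        if times.shape != (positions.shape[0],):
            raise ValueError("times and positions disagree on frame count")
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            nominal = 1.0 / frame_rate
            if np.any(np.abs(dt - nominal) > TIMESTAMP_TOLERANCE):
                raise ValueError(
                    f"non-uniform sampling: frame intervals deviate more than "
                    f"{TIMESTAMP_TOLERANCE * 1e3:.0f} ms from {nominal:.4f} s"
                )
        if not np.all(np.isfinite(positions)):
            raise ValueError("non-finite joint coordinates in trace")
        self.times = times
        self.positions = positions
        self.frame_rate = float(frame_rate)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if len(self) > 1 else 0.0

    def pose(self, i: int) -> SkeletonPose:
        return SkeletonPose.from_array(float(self.times[i]), self.positions[i])

    def poses(self) -> Iterable[SkeletonPose]:
        for i in range(len(self)):
            yield self.pose(i)

    def joint(self, joint: JointName) -> np.ndarray:
        """(T, 3) trajectory of one joint."""
        return self.positions[:, JOINT_INDEX[joint], :]

    @classmethod
    def from_poses(cls, poses: Sequence[SkeletonPose],
                   frame_rate: float = DEFAULT_FRAME_RATE) -> "MotionTrace":
        times = np.array([p.timestamp for p in poses], dtype=float)
        positions = np.stack([p.as_array() for p in poses])
        return cls(times, positions, frame_rate)


# ---------------------------------------------------------------------------
# Skeleton fitting
# ---------------------------------------------------------------------------

def fit_skeleton_to_pose(pose: SkeletonPose) -> SkeletonModel:
    """Adapt bone lengths to a subject: each length is the inter-joint distance.

    Raises :class:`InvalidPoseError` if any parent/child pair coincides
    (a degenerate capture frame).
    """
    lengths: dict[tuple[JointName, JointName], float] = {}
    for child, parent in PARENT.items():
        if parent is None:
            continue
        d = float(np.linalg.norm(pose[child] - pose[parent]))
        if d <= 0.0:
            raise InvalidPoseError(
                f"degenerate pose: {child.value} coincides with its parent {parent.value}"
            )
        lengths[(parent, child)] = d
    return SkeletonModel(lengths)


def forward_place(model: SkeletonModel, reference: SkeletonPose,
                  root_position: np.ndarray | None = None) -> SkeletonPose:
    """Rebuild a pose from the model's bone lengths and the reference pose's
    segment directions, walking the tree from the root.

    With ``model = fit_skeleton_to_pose(reference)`` this reproduces the
    reference positions exactly.
    """
    root = reference[JointName.HIP_CENTER] if root_position is None else np.asarray(root_position, float)
    out: dict[JointName, np.ndarray] = {JointName.HIP_CENTER: root.astype(float)}
    stack = list(CHILDREN[JointName.HIP_CENTER])
    while stack:
        child = stack.pop()
        parent = PARENT[child]
        direction = reference[child] - reference[parent]
        n = np.linalg.norm(direction)
        if n <= 0:
            raise InvalidPoseError(
                f"degenerate reference: {child.value} coincides with {parent.value}"
            )
        out[child] = out[parent] + direction * (model.length(parent, child) / n)
        stack.extend(CHILDREN[child])
    return SkeletonPose(reference.timestamp, out)


# Canonical standing rest geometry (metres, scale 1 ≈ a small adult).
_REST_OFFSETS: dict[JointName, tuple[float, float, float]] = {
    JointName.HIP_CENTER: (0.0, 0.0, 0.95),
    JointName.SPINE: (0.0, 0.0, 1.20),
    JointName.SHOULDER_CENTER: (0.0, 0.0, 1.40),
    JointName.HEAD: (0.0, 0.0, 1.58),
    JointName.SHOULDER_LEFT: (0.0, 0.18, 1.40),
    JointName.ELBOW_LEFT: (0.0, 0.18, 1.12),
    JointName.WRIST_LEFT: (0.0, 0.18, 0.87),
    JointName.HAND_LEFT: (0.0, 0.18, 0.79),
    JointName.SHOULDER_RIGHT: (0.0, -0.18, 1.40),
    JointName.ELBOW_RIGHT: (0.0, -0.18, 1.12),
    JointName.WRIST_RIGHT: (0.0, -0.18, 0.87),
    JointName.HAND_RIGHT: (0.0, -0.18, 0.79),
    JointName.HIP_LEFT: (0.0, 0.09, 0.95),
    JointName.KNEE_LEFT: (0.0, 0.09, 0.55),
    JointName.ANKLE_LEFT: (0.0, 0.09, 0.17),
    JointName.FOOT_LEFT: (0.12, 0.09, 0.10),
    JointName.HIP_RIGHT: (0.0, -0.09, 0.95),
    JointName.KNEE_RIGHT: (0.0, -0.09, 0.55),
    JointName.ANKLE_RIGHT: (0.0, -0.09, 0.17),
    JointName.FOOT_RIGHT: (0.12, -0.09, 0.10),
}


def default_rest_pose(scale: float = 1.0, timestamp: float = 0.0) -> SkeletonPose:
    """Standing rest pose: arms hanging at the sides, facing +x."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return SkeletonPose(
        timestamp,
        {j: scale * np.array(off, dtype=float) for j, off in _REST_OFFSETS.items()},
    )


def default_skeleton_model(scale: float = 1.0) -> SkeletonModel:
    """Bone-length model of the canonical standing rest pose."""
    return fit_skeleton_to_pose(default_rest_pose(scale))


# ---------------------------------------------------------------------------
# Two-bone analytic inverse kinematics
# ---------------------------------------------------------------------------

DEFAULT_BEND_HINT = np.array([1.0, 0.0, 0.0])  # slight forward elbow/knee


def solve_two_bone_ik(
    root: np.ndarray,
    target: np.ndarray,
    len_upper: float,
    len_lower: float,
    bend_hint: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Place the middle and end joints of a two-segment limb.

    The end joint lands on ``target`` whenever it lies inside the annulus
    ``[|len_upper − len_lower|, len_upper + len_lower]`` around ``root``;
    otherwise it is clamped to the nearest reachable point on the
    root→target ray.  The bend plane contains ``bend_hint``; a hint parallel
    to the root→target axis falls back to the default forward hint.
    """
    if len_upper <= 0 or len_lower <= 0:
        raise ValueError("segment lengths must be positive")
    root = np.asarray(root, dtype=float)
    target = np.asarray(target, dtype=float)
    hint = DEFAULT_BEND_HINT if bend_hint is None else np.asarray(bend_hint, dtype=float)

    to_target = target - root
    dist = float(np.linalg.norm(to_target))
    lo, hi = abs(len_upper - len_lower), len_upper + len_lower

    if dist < 1e-12:
        # Root and target coincide: the reach direction is undefined, take
        # the bend hint as axis (documented tie-break).
        axis = hint / np.linalg.norm(hint)
        d = min(max(0.0, lo), hi)
    else:
        axis = to_target / dist
        d = min(max(dist, lo), hi)

    # Law of cosines: distance from root to the mid joint's projection.
    a = (len_upper**2 - len_lower**2 + d**2) / (2.0 * d) if d > 0 else 0.0
    h_sq = len_upper**2 - a**2
    h = np.sqrt(max(h_sq, 0.0))

    # Bend direction: hint component orthogonal to the axis.
    perp = hint - np.dot(hint, axis) * axis
    n = np.linalg.norm(perp)
    if n < 1e-12:
        perp = DEFAULT_BEND_HINT - np.dot(DEFAULT_BEND_HINT, axis) * axis
        n = np.linalg.norm(perp)
        if n < 1e-12:  # axis is the default hint itself
            fallback = np.array([0.0, 1.0, 0.0])
            perp = fallback - np.dot(fallback, axis) * axis
            n = np.linalg.norm(perp)
    perp /= n

    mid = root + a * axis + h * perp
    end = root + d * axis
    # Renormalise the lower segment against accumulated rounding.
    lower = end - mid
    ln = np.linalg.norm(lower)
    if ln > 0:
        end = mid + lower * (len_lower / ln)
    return mid, end


def solve_two_bone_ik_batch(
    roots: np.ndarray,
    targets: np.ndarray,
    len_upper: float,
    len_lower: float,
    bend_hint: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`solve_two_bone_ik` over (T, 3) arrays."""
    if len_upper <= 0 or len_lower <= 0:
        raise ValueError("segment lengths must be positive")
    roots = np.asarray(roots, dtype=float)
    targets = np.asarray(targets, dtype=float)
    hint = DEFAULT_BEND_HINT if bend_hint is None else np.asarray(bend_hint, dtype=float)
    hint = hint / np.linalg.norm(hint)

    to_target = targets - roots
    dist = np.linalg.norm(to_target, axis=1)
    lo, hi = abs(len_upper - len_lower), len_upper + len_lower

    safe = dist > 1e-12
    axis = np.where(safe[:, None], to_target / np.where(safe, dist, 1.0)[:, None], hint)
    d = np.clip(np.where(safe, dist, lo), max(lo, 0.0), hi)

    a = (len_upper**2 - len_lower**2 + d**2) / (2.0 * d)
    h = np.sqrt(np.maximum(len_upper**2 - a**2, 0.0))

    dot = axis @ hint
    perp = hint[None, :] - dot[:, None] * axis
    n = np.linalg.norm(perp, axis=1)
    # Degenerate rows (axis ∥ hint): fall back to a lateral bend.
    bad = n < 1e-12
    if np.any(bad):
        fallback = np.array([0.0, 1.0, 0.0])
        p2 = fallback[None, :] - (axis[bad] @ fallback)[:, None] * axis[bad]
        perp[bad] = p2
        n[bad] = np.linalg.norm(p2, axis=1)
    perp /= n[:, None]

    mid = roots + a[:, None] * axis + h[:, None] * perp
    end = roots + d[:, None] * axis
    lower = end - mid
    ln = np.linalg.norm(lower, axis=1)
    end = mid + lower * (len_lower / np.where(ln > 0, ln, 1.0))[:, None]
    return mid, end
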