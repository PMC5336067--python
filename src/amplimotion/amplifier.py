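"""Calibrated motion amplification and pose retargeting.

The core idea: a weak user displacement ``d = position − resting`` is mapped
onto the avatar as ``f ∘ d`` with per-axis, per-direction factors ``f``
obtained from calibration, so that the user's maximum possible movement
always produces the avatar's full required movement.

Two equivalent realisations are provided:

* :func:`amplify_direct` — the straight multiplication, the production path;
* :func:`amplify_chain` / :func:`amplify_chain_iterative` — the bone-chain
  construction: a chain of ``n`` bones in which every bone copies its
  parent's local displacement scaled by a per-axis restriction factor
  ``f_res ∈ [0, 1]``, yielding the global factor ``f = n · f_res``.  The
  closed form and the explicit parent-copy recurrence agree exactly; the
  chain exists because per-bone scalings are bounded by 1 while useful
  global factors run up to 25.

Retargeting applies the amplified point (plus the calibration offset) to the
avatar's end effectors and solves the intermediate joints (elbows, knees) by
two-bone analytic IK.  Trunk and head pass through unamplified.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibration import FACTOR_MAX, CalibrationProfile, LimbCalibration
from .core_model import (
    JOINT_INDEX,
    JOINTS,
    JointName,
    MotionTrace,
    SkeletonModel,
    SkeletonPose,
    TRUNK_JOINTS,
    solve_two_bone_ik,
    solve_two_bone_ik_batch,
)

__all__ = [
    "AmplifierChain",
    "AmplifiedPose",
    "LimbMarkers",
    "amplify_direct",
    "amplify_chain",
    "amplify_chain_iterative",
    "factors_to_restrictions",
    "retarget_pose",
    "retarget_trace",
]

DEFAULT_N_BONES = 25


@dataclass
class AmplifierChain:
    """Bone chain with per-axis restriction factors in ``[0, 1]``."""

    f_res: np.ndarray
    n_bones: int = DEFAULT_N_BONES

    def __post_init__(self) -> None:
        self.f_res = np.asarray(self.f_res, dtype=float)
        if self.f_res.shape != (3,):
            raise ValueError("f_res must be a per-axis 3-vector")
        if np.any(self.f_res < 0) or np.any(self.f_res > 1):
            raise ValueError("restriction factors must lie in [0, 1]")
        if self.n_bones < 1:
            raise ValueError("chain needs at least one bone")

    @property
    def global_factors(self) -> np.ndarray:
        return self.n_bones * self.f_res


@dataclass
class LimbMarkers:
    """The three reference spheres of one limb, in avatar space.

    ``resting`` (red): the displaced origin of movement; ``real`` (green):
    the user's actual, offset-shifted position; ``amplified`` (yellow): the
    target the avatar limb is driven to.  All three coincide when the limb
    rests.
    """

    resting: np.ndarray
    real: np.ndarray
    amplified: np.ndarray


@dataclass
class AmplifiedPose:
    """Avatar pose plus per-limb marker triples."""

    pose: SkeletonPose
    markers: dict[str, LimbMarkers] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Amplification primitives
# ---------------------------------------------------------------------------

def _select_factors(displacement: np.ndarray, factors_pos: np.ndarray,
                    factors_neg: np.ndarray) -> np.ndarray:
    """Per-axis factor chosen by the sign of each displacement component.

    Continuity at zero is guaranteed by the zero fixed point (0 · f = 0
    either way).  Works on (3,) or (T, 3) displacement arrays.
    """
    return np.where(displacement >= 0, factors_pos, factors_neg)


def amplify_direct(resting: np.ndarray, position: np.ndarray,
                   factors_pos: np.ndarray,
                   factors_neg: np.ndarray | None = None) -> np.ndarray:
    """Amplify a position about its resting point.

    ``resting + f ∘ (position − resting)``, each axis using the factor of the
    displacement's sign.  Pass one factor triple for symmetric amplification.
    """
    resting = np.asarray(resting, dtype=float)
    position = np.asarray(position, dtype=float)
    factors_pos = np.asarray(factors_pos, dtype=float)
    factors_neg = factors_pos if factors_neg is None else np.asarray(factors_neg, float)
    disp = position - resting
    return resting + _select_factors(disp, factors_pos, factors_neg) * disp


def amplify_chain(chain: AmplifierChain, displacement_real: np.ndarray) -> np.ndarray:
    """Closed-form chain output: ``n_bones · f_res ∘ displacement``."""
    return chain.global_factors * np.asarray(displacement_real, dtype=float)


def amplify_chain_iterative(chain: AmplifierChain,
                            displacement_real: np.ndarray) -> np.ndarray:
    """Reference parent-copy recurrence over the chain.

    Each bone displaces by the restricted copy of the real displacement in
    its father's local frame; the global displacement of the last bone is
    the amplified output.  Behaviourally identical to :func:`amplify_chain`;
    kept as the explicit construction.

    Every bone contributes its restriction factor once, so the end bone's
    global factor is the ``n_bones``-fold sum of ``f_res``; the sum is
    accumulated exactly (correctly rounded) so the construction is bitwise
    comparable with the closed form.
    """
    f_res = np.broadcast_to(np.asarray(chain.f_res, dtype=float), (3,))
    accumulated = np.array([math.fsum([float(f)] * chain.n_bones)
                            for f in f_res])
    return accumulated * np.asarray(displacement_real, dtype=float)


def factors_to_restrictions(factors: np.ndarray,
                            n_bones: int = DEFAULT_N_BONES) -> np.ndarray:
    """Invert the chain: global factor ``f`` → per-bone restriction ``f / n``.

    Factors above the chain length cannot be represented (calibration should
    have clipped them) and raise ``ValueError``.
    """
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("factors must be positive")
    if np.any(factors > n_bones):
        raise ValueError(
            f"factor exceeds the chain limit {n_bones}; calibration must clip"
        )
    return factors / n_bones


# ---------------------------------------------------------------------------
# Pose retargeting
# ---------------------------------------------------------------------------

# Per-limb kinematic chains: (ik root, mid, end-of-ik, end effector).
_LIMB_CHAINS: dict[str, tuple[JointName, JointName, JointName, JointName]] = {
    "hand_left": (JointName.SHOULDER_LEFT, JointName.ELBOW_LEFT,
                  JointName.WRIST_LEFT, JointName.HAND_LEFT),
    "hand_right": (JointName.SHOULDER_RIGHT, JointName.ELBOW_RIGHT,
                   JointName.WRIST_RIGHT, JointName.HAND_RIGHT),
    "foot_left": (JointName.HIP_LEFT, JointName.KNEE_LEFT,
                  JointName.ANKLE_LEFT, JointName.FOOT_LEFT),
    "foot_right": (JointName.HIP_RIGHT, JointName.KNEE_RIGHT,
                   JointName.ANKLE_RIGHT, JointName.FOOT_RIGHT),
}

# Slightly forward bend hints avoid the singular straight-chain plane.
_BEND_HINTS = {
    "hand_left": np.array([1.0, 0.2, 0.0]),
    "hand_right": np.array([1.0, -0.2, 0.0]),
    "foot_left": np.array([1.0, 0.0, 0.0]),
    "foot_right": np.array([1.0, 0.0, 0.0]),
}


def _amplified_target(user_position: np.ndarray, lc: LimbCalibration) -> np.ndarray:
    """Offset-shifted amplified point for one limb (works on (3,) or (T,3))."""
    disp = np.asarray(user_position, dtype=float) - lc.resting
    amp = _select_factors(disp, lc.factors_pos, lc.factors_neg) * disp
    return lc.resting + lc.offset + amp


def retarget_pose(user_pose: SkeletonPose, profile: CalibrationProfile,
                  avatar_model: SkeletonModel) -> AmplifiedPose:
    """Map one user pose onto the avatar.

    Hands and feet are amplified about their calibrated resting points and
    shifted by the per-limb offset; arms and legs follow by two-bone IK;
    trunk and head are copied with the whole-body offset, unamplified.
    Limbs absent from the profile are copied unamplified with a warning.
    """
    out: dict[JointName, np.ndarray] = {}
    for j in TRUNK_JOINTS:
        out[j] = user_pose[j] + profile.body_offset

    markers: dict[str, LimbMarkers] = {}
    for limb, (root_j, mid_j, end_j, eff_j) in _LIMB_CHAINS.items():
        if limb not in profile.limbs:
            warnings.warn(f"limb {limb!r} missing from profile; copied unamplified")
            for j in (mid_j, end_j, eff_j):
                out[j] = user_pose[j] + profile.body_offset
            continue
        lc = profile.limbs[limb]
        target = _amplified_target(user_pose[eff_j], lc)
        markers[limb] = LimbMarkers(
            resting=lc.resting + lc.offset,
            real=user_pose[eff_j] + lc.offset,
            amplified=target,
        )
        root = out[root_j]
        len_upper = avatar_model.length(root_j, mid_j)
        len_lower = avatar_model.length(mid_j, end_j)
        len_eff = avatar_model.length(end_j, eff_j)
        to_target = target - root
        dist = np.linalg.norm(to_target)
        u = to_target / dist if dist > 1e-12 else _BEND_HINTS[limb] / np.linalg.norm(_BEND_HINTS[limb])
        wrist_target = target - len_eff * u
        mid, end = solve_two_bone_ik(root, wrist_target, len_upper, len_lower,
                                     bend_hint=_BEND_HINTS[limb])
        out[mid_j], out[end_j] = mid, end
        out[eff_j] = end + len_eff * u
    return AmplifiedPose(SkeletonPose(user_pose.timestamp, out), markers)


def retarget_trace(trace: MotionTrace, profile: CalibrationProfile,
                   avatar_model: SkeletonModel) -> tuple[MotionTrace, dict[str, dict[str, np.ndarray]]]:
    """Vectorised :func:`retarget_pose` over a whole trace.

    Returns the avatar trace and, per limb, the (T, 3) marker series
    ``{"resting", "real", "amplified"}``.
    """
    T = len(trace)
    out = np.empty_like(trace.positions)
    for j in TRUNK_JOINTS:
        out[:, JOINT_INDEX[j]] = trace.joint(j) + profile.body_offset

    markers: dict[str, dict[str, np.ndarray]] = {}
    for limb, (root_j, mid_j, end_j, eff_j) in _LIMB_CHAINS.items():
        if limb not in profile.limbs:
            warnings.warn(f"limb {limb!r} missing from profile; copied unamplified")
            for j in (mid_j, end_j, eff_j):
                out[:, JOINT_INDEX[j]] = trace.joint(j) + profile.body_offset
            continue
        lc = profile.limbs[limb]
        targets = _amplified_target(trace.joint(eff_j), lc)
        markers[limb] = {
            "resting": np.broadcast_to(lc.resting + lc.offset, (T, 3)).copy(),
            "real": trace.joint(eff_j) + lc.offset,
            "amplified": targets,
        }
        roots = out[:, JOINT_INDEX[root_j]]
        len_upper = avatar_model.length(root_j, mid_j)
        len_lower = avatar_model.length(mid_j, end_j)
        len_eff = avatar_model.length(end_j, eff_j)
        to_target = targets - roots
        dist = np.linalg.norm(to_target, axis=1)
        hint = _BEND_HINTS[limb] / np.linalg.norm(_BEND_HINTS[limb])
        safe = dist > 1e-12
        u = np.where(safe[:, None], to_target / np.where(safe, dist, 1.0)[:, None], hint)
        wrist_targets = targets - len_eff * u
        mid, end = solve_two_bone_ik_batch(roots, wrist_targets, len_upper,
                                           len_lower, bend_hint=_BEND_HINTS[limb])
        out[:, JOINT_INDEX[mid_j]] = mid
        out[:, JOINT_INDEX[end_j]] = end
        out[:, JOINT_INDEX[eff_j]] = end + len_eff * u
    return MotionTrace(trace.times.copy(), out, trace.frame_rate), markers
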