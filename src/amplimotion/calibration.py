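"""Per-user calibration: resting point, movement ranges, amplification factors.

A calibration session asks the player to rest, then to stretch each limb as
far as possible in every direction.  From the recorded trace this module
derives, per tracked limb (both hands and both feet):

* the **resting point** — the origin from which every displacement is
  measured (the "red sphere"),
* per-axis, per-direction **ranges** — how far the player can actually move,
* per-axis, per-direction **amplification factors** — avatar required range
  divided by the player's range, clipped to ``[1, 25]``,
* an **offset** that relocates the avatar's reference point (e.g. a seated
  player's hand resting at hip height maps onto a standing avatar's hand
  hanging at its side).

All quantities live in displacement space relative to the resting point, so
a profile is invariant to where the player sits in front of the sensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import (
    JointName,
    MotionTrace,
    SkeletonModel,
    SkeletonPose,
    default_rest_pose,
    forward_place,
)

__all__ = [
    "AXES",
    "FACTOR_MIN",
    "FACTOR_MAX",
    "UNUSABLE_RANGE",
    "LIMB_JOINTS",
    "LimbCalibration",
    "CalibrationProfile",
    "record_resting",
    "measure_range",
    "compute_factors",
    "compute_offset",
    "calibrate",
    "avatar_rest_pose",
    "avatar_required_range",
]

AXES = ("x", "y", "z")
FACTOR_MIN = 1.0   # never attenuate a capable user
FACTOR_MAX = 25.0  # amplifier chain length
UNUSABLE_RANGE = 0.01  # m; below this an axis/direction is flagged unusable
PROFILE_VERSION = "1"

LIMB_JOINTS: dict[str, JointName] = {
    "hand_left": JointName.HAND_LEFT,
    "hand_right": JointName.HAND_RIGHT,
    "foot_left": JointName.FOOT_LEFT,
    "foot_right": JointName.FOOT_RIGHT,
}


@dataclass
class LimbCalibration:
    """Calibration of one end effector (hand or foot)."""

    resting: np.ndarray          # (3,) user-space resting point
    range_pos: np.ndarray        # (3,) max displacement along +axis, >= 0
    range_neg: np.ndarray        # (3,) max displacement along -axis, >= 0
    factors_pos: np.ndarray      # (3,) in [1, 25]
    factors_neg: np.ndarray      # (3,)
    offset: np.ndarray           # (3,) avatar resting point - user resting point
    unusable_pos: np.ndarray = field(default_factory=lambda: np.zeros(3, bool))
    unusable_neg: np.ndarray = field(default_factory=lambda: np.zeros(3, bool))

    def __post_init__(self) -> None:
        for name in ("resting", "range_pos", "range_neg",
                     "factors_pos", "factors_neg", "offset"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.unusable_pos = np.asarray(self.unusable_pos, dtype=bool)
        self.unusable_neg = np.asarray(self.unusable_neg, dtype=bool)
        if np.any(self.range_pos < 0) or np.any(self.range_neg < 0):
            raise ValueError("ranges must be non-negative")
        for f in (self.factors_pos, self.factors_neg):
            if np.any(f < FACTOR_MIN - 0.05) or np.any(f > FACTOR_MAX):
                raise ValueError(f"factors must lie in [{FACTOR_MIN}, {FACTOR_MAX}]")

    def amplified_range_pos(self) -> np.ndarray:
        """Avatar-space range reached at the user's maximum (+ direction)."""
        return self.range_pos * self.factors_pos

    def amplified_range_neg(self) -> np.ndarray:
        return self.range_neg * self.factors_neg


@dataclass
class CalibrationProfile:
    """Complete user profile: one LimbCalibration per tracked limb plus a
    whole-body offset applied to unamplified (trunk) joints."""

    limbs: dict[str, LimbCalibration]
    body_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    version: str = PROFILE_VERSION

    def __post_init__(self) -> None:
        unknown = set(self.limbs) - set(LIMB_JOINTS)
        if unknown:
            raise ValueError(f"unknown limbs in profile: {sorted(unknown)}")
        self.body_offset = np.asarray(self.body_offset, dtype=float)


# ---------------------------------------------------------------------------
# Resting point
# ---------------------------------------------------------------------------

def _joint_of(limb: str | JointName) -> JointName:
    if isinstance(limb, JointName):
        return limb
    try:
        return LIMB_JOINTS[limb]
    except KeyError:
        raise KeyError(f"unknown limb {limb!r}; expected one of {sorted(LIMB_JOINTS)}")


def record_resting(trace: MotionTrace, limb: str | JointName,
                   window: float = 1.0) -> np.ndarray:
    """Per-axis median of the limb position over the stillest window.

    The stillest window is the contiguous span of ``window`` seconds with the
    minimum summed speed of the limb joint.  Speed is measured on a smoothed
    (0.5 s moving average) copy of the trajectory: per-frame sensor jitter
    otherwise dominates the raw frame-to-frame speed, so for users with very
    small genuine movements the selection would degenerate to picking an
    essentially random window — possibly mid-movement, biasing the resting
    point.  Smoothing suppresses the jitter path almost entirely while the
    net displacement of any genuine movement inside a window survives it.
    The reported position is the jitter-robust per-axis median of the *raw*
    samples inside the chosen window.
    """
    if window < 1.0:
        raise ValueError("resting window must be at least 1 s")
    joint = _joint_of(limb)
    traj = trace.joint(joint)
    w = int(round(window * trace.frame_rate))
    if len(trace) < w or w < 2:
        raise ValueError(
            f"trace too short for a {window} s resting window "
            f"({len(trace)} frames at {trace.frame_rate} Hz)"
        )
    k = min(max(1, int(round(trace.frame_rate / 2.0))), len(traj))
    kernel = np.ones(k) / k
    smooth = np.column_stack([np.convolve(traj[:, ax], kernel, mode="valid")
                              for ax in range(3)])
    step_speed = np.linalg.norm(np.diff(smooth, axis=0), axis=1)
    w_s = min(w - 1, len(step_speed))
    # Summed speed inside each window of w_s steps.
    csum = np.concatenate([[0.0], np.cumsum(step_speed)])
    sums = csum[w_s:] - csum[:-w_s]
    start = int(np.argmin(sums))
    return np.median(traj[start:start + w], axis=0)


# ---------------------------------------------------------------------------
# Ranges
# ---------------------------------------------------------------------------

def _despike(values: np.ndarray, window: int = 5, k: float = 3.0) -> np.ndarray:
    """Hampel filter: replace samples deviating more than ``k`` robust
    standard deviations from their local median by that median.

    Depth sensors occasionally teleport a joint ("scattering") for a frame or
    two.  A rolling-median *filter* would reject those too, but at the cost
    of inflating the variance of every clean sample; the Hampel filter only
    touches the outliers, so subsequent averaging retains the full
    ``1/sqrt(n)`` noise reduction.  The robust scale is the MAD of the
    residuals over the whole series; when it is zero (noiseless data) any
    non-zero residual counts as a spike.
    """
    values = np.asarray(values, dtype=float)
    if values.size < window:
        return values.copy()
    half = window // 2
    padded = np.pad(values, half, mode="edge")
    med = np.median(np.lib.stride_tricks.sliding_window_view(padded, window), axis=1)
    resid = np.abs(values - med)
    scale = 1.4826 * np.median(resid)
    return np.where(resid > k * scale, med, values)


def _robust_max(values: np.ndarray, sustain: int = 5, average: int = 75) -> float:
    """Sustained maximum: the largest mean level held for ``average``
    consecutive frames (2.5 s at 30 Hz).

    A genuine maximal stretch is *held* (the calibration protocol asks for a
    three-second hold), so the peak level can be estimated by averaging
    rather than by taking an extremum — extremum estimators applied to raw
    jittery samples are biased by the order of one jitter standard
    deviation, which for small movement ranges is a material fraction of the
    range itself.  Two passes:

    1. a Hampel despike over ``sustain`` frames removes teleports of up to
       ``sustain // 2`` frames exactly (see :func:`_despike`),
    2. a rolling mean over ``average`` frames, whose maximum is returned.

    Plateaus held for at least ``average`` frames survive both passes
    exactly in the noiseless case; shorter excursions are attenuated but
    still register.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    despiked = _despike(values, window=sustain)
    if despiked.size < average:
        return float(np.max(despiked))
    smooth = np.lib.stride_tricks.sliding_window_view(despiked, average).mean(axis=1)
    return float(np.max(smooth))


def measure_range(trace: MotionTrace, limb: str | JointName,
                  resting: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis maximal displacement from the resting point, both directions.

    Returns ``(range_pos, range_neg)`` — magnitudes, clipped at zero, after
    spike rejection (see :func:`_robust_max`).
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    disp = trace.joint(_joint_of(limb)) - np.asarray(resting, dtype=float)
    range_pos = np.array([max(0.0, _robust_max(disp[:, ax])) for ax in range(3)])
    range_neg = np.array([max(0.0, _robust_max(-disp[:, ax])) for ax in range(3)])
    return range_pos, range_neg


# ---------------------------------------------------------------------------
# Factors and offset
# ---------------------------------------------------------------------------

def compute_factors(user_ranges: np.ndarray, avatar_ranges: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Amplification factors: avatar required range / user range.

    Clipped to ``[1, 25]``.  Axes with a user range below 1 cm cannot be
    controlled reliably and are flagged unusable with factor 1.
    Returns ``(factors, unusable)``.
    """
    user = np.asarray(user_ranges, dtype=float)
    avatar = np.asarray(avatar_ranges, dtype=float)
    unusable = user < UNUSABLE_RANGE
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(unusable, 1.0, avatar / np.where(unusable, 1.0, user))
    return np.clip(raw, FACTOR_MIN, FACTOR_MAX), unusable


def compute_offset(user_resting: np.ndarray, avatar_resting: np.ndarray) -> np.ndarray:
    """Translation taking the user's resting point onto the avatar's."""
    return np.asarray(avatar_resting, dtype=float) - np.asarray(user_resting, dtype=float)


# ---------------------------------------------------------------------------
# Avatar reference geometry
# ---------------------------------------------------------------------------

def avatar_rest_pose(avatar_model: SkeletonModel) -> SkeletonPose:
    """Canonical standing rest pose of the avatar, scaled to its bone lengths."""
    return forward_place(avatar_model, default_rest_pose())


def avatar_required_range(avatar_model: SkeletonModel, limb: str) -> float:
    """Range the avatar limb must cover: its full reach (arm or leg length).

    Whatever the avatar's size, its sword swing must span the full arm; the
    required range is therefore derived from bone lengths, not hard-coded.
    """
    joint = _joint_of(limb)
    side = "left" if joint.value.endswith("left") else "right"
    if joint in (JointName.HAND_LEFT, JointName.HAND_RIGHT):
        return avatar_model.arm_length(side)
    return avatar_model.leg_length(side)


# ---------------------------------------------------------------------------
# Full calibration
# ---------------------------------------------------------------------------

def calibrate(trace: MotionTrace, avatar_model: SkeletonModel,
              limbs: tuple[str, ...] = ("hand_left", "hand_right",
                                        "foot_left", "foot_right"),
              resting_window: float = 4.0) -> CalibrationProfile:
    """Derive a complete profile from a rest-then-maximal-stretch trace.

    The default resting window (4 s) is deliberately longer than any held
    stretch in the calibration protocol (3 s), so the stillest window can
    only lie inside the genuine resting phase; a shorter window could be
    just as still on a held maximal stretch, which would wreck every range.
    The long window also averages sensor jitter out of the resting point,
    which matters as much as the peak estimate when ranges are small.
    """
    rest = avatar_rest_pose(avatar_model)
    out: dict[str, LimbCalibration] = {}
    for limb in limbs:
        joint = _joint_of(limb)
        resting = record_resting(trace, limb, window=resting_window)
        range_pos, range_neg = measure_range(trace, limb, resting)
        required = avatar_required_range(avatar_model, limb)
        f_pos, u_pos = compute_factors(range_pos, np.full(3, required))
        f_neg, u_neg = compute_factors(range_neg, np.full(3, required))
        offset = compute_offset(resting, rest[joint])
        out[limb] = LimbCalibration(
            resting=resting, range_pos=range_pos, range_neg=range_neg,
            factors_pos=f_pos, factors_neg=f_neg, offset=offset,
            unusable_pos=u_pos, unusable_neg=u_neg,
        )
    hip_rest = record_resting(trace, JointName.HIP_CENTER, window=resting_window)
    body_offset = compute_offset(hip_rest, rest[JointName.HIP_CENTER])
    return CalibrationProfile(limbs=out, body_offset=body_offset)
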