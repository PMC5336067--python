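"""Measurement gadgets: the Rope, the Accelerometer, and control gestures.

The **Rope** is an imaginary elastic band between two attachment points
(joints or fixed world points) that fires events when its length crosses a
trigger threshold — stretching beyond it ("above" mode, e.g. arm spreading)
or shrinking within it ("below" mode, e.g. a hand clap or grabbing a rung).
A hysteresis band (default 10 % of the trigger length) prevents sensor
jitter from chattering events.

The **Accelerometer** reports the instantaneous speed of an attached point
(despite its name it measures speed, not acceleration) via a backward finite
difference over a configurable window.

**Control gestures** distinguish game-control movements (opening a menu)
from exercise movements: a pose predicate held continuously for a dwell time
fires a control event, and exercise processing for the involved limb is
suppressed while the gesture is held.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core_model import JointName, MotionTrace, SkeletonPose

__all__ = [
    "Rope",
    "Accelerometer",
    "GadgetEvent",
    "GestureSpec",
    "rope_length",
    "rope_lengths",
    "rope_events",
    "speed",
    "speed_series",
    "detect_control_gesture",
    "suppression_mask",
]

Attachment = JointName | np.ndarray | tuple | list


@dataclass
class Rope:
    end_a: Attachment
    end_b: Attachment
    trigger_length: float
    hysteresis: float | None = None  # default: 10 % of trigger_length
    mode: str = "above"  # "above": activate on stretch; "below": on approach

    def __post_init__(self) -> None:
        if self.trigger_length <= 0:
            raise ValueError("trigger_length must be positive")
        if self.hysteresis is None:
            self.hysteresis = 0.1 * self.trigger_length
        if self.hysteresis < 0:
            raise ValueError("hysteresis must be non-negative")
        if self.mode not in ("above", "below"):
            raise ValueError("mode must be 'above' or 'below'")


@dataclass
class Accelerometer:
    attachment: Attachment
    window: int = 2  # frames of backward differencing

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be at least 1 frame")


@dataclass
class GadgetEvent:
    time: float
    gadget: str
    kind: str  # "activated" | "released"
    value: float


@dataclass
class GestureSpec:
    """Dwell gesture: ``predicate(pose) -> bool`` held for ``dwell`` seconds."""

    predicate: Callable[[SkeletonPose], bool]
    dwell: float
    name: str = "gesture"
    limb: str | None = None  # limb whose exercise processing is suppressed

    def __post_init__(self) -> None:
        if self.dwell < 0.5:
            raise ValueError("dwell must be at least 0.5 s to separate control "
                             "gestures from exercise movement")


def _resolve(attachment: Attachment, pose: SkeletonPose) -> np.ndarray:
    if isinstance(attachment, JointName):
        return pose[attachment]
    arr = np.asarray(attachment, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"attachment must be a joint or a 3-vector, got {attachment!r}")
    return arr


def _resolve_series(attachment: Attachment, trace: MotionTrace) -> np.ndarray:
    if isinstance(attachment, JointName):
        return trace.joint(attachment)
    arr = np.asarray(attachment, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"attachment must be a joint or a 3-vector, got {attachment!r}")
    return np.broadcast_to(arr, (len(trace), 3))


def rope_length(pose: SkeletonPose, rope: Rope) -> float:
    """Euclidean distance between the rope's resolved endpoints."""
    return float(np.linalg.norm(_resolve(rope.end_a, pose) - _resolve(rope.end_b, pose)))


def rope_lengths(trace: MotionTrace, rope: Rope) -> np.ndarray:
    """(T,) rope length series over a trace."""
    a = _resolve_series(rope.end_a, trace)
    b = _resolve_series(rope.end_b, trace)
    return np.linalg.norm(a - b, axis=1)


def events_from_lengths(times: np.ndarray, lengths: np.ndarray, rope: Rope,
                        gadget_id: str = "rope") -> list[GadgetEvent]:
    """Threshold/hysteresis event detection on a precomputed length series."""
    sign = 1.0 if rope.mode == "above" else -1.0
    # In the active state the rope must re-cross by `hysteresis` to release.
    activate = sign * (lengths - rope.trigger_length) >= 0
    release = sign * (lengths - rope.trigger_length) < -rope.hysteresis

    events: list[GadgetEvent] = []
    active = False
    for t, ln, act, rel in zip(times, lengths, activate, release):
        if not active and act:
            events.append(GadgetEvent(float(t), gadget_id, "activated", float(ln)))
            active = True
        elif active and rel:
            events.append(GadgetEvent(float(t), gadget_id, "released", float(ln)))
            active = False
    return events


def rope_events(trace: MotionTrace, rope: Rope,
                gadget_id: str = "rope") -> list[GadgetEvent]:
    """Activation/release events of a rope over a trace.

    The first frame is evaluated directly against the threshold, so a rope
    that starts past its trigger activates at t = 0.  Events strictly
    alternate; oscillation inside the hysteresis band produces none.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    return events_from_lengths(trace.times, rope_lengths(trace, rope), rope, gadget_id)


# ---------------------------------------------------------------------------
# Accelerometer
# ---------------------------------------------------------------------------

def speed(trace: MotionTrace, index: int, accelerometer: Accelerometer) -> float:
    """Backward-difference speed of the attachment at one frame (m/s)."""
    w = accelerometer.window
    if index < w:
        raise ValueError(f"speed undefined at frame {index}: needs {w} prior frames")
    traj = _resolve_series(accelerometer.attachment, trace)
    dt = float(trace.times[index] - trace.times[index - w])
    return float(np.linalg.norm(traj[index] - traj[index - w]) / dt)


def speed_series(trace: MotionTrace, accelerometer: Accelerometer) -> np.ndarray:
    """(T,) speed series; the first ``window`` entries are NaN (undefined)."""
    w = accelerometer.window
    traj = _resolve_series(accelerometer.attachment, trace)
    out = np.full(len(trace), np.nan)
    if len(trace) > w:
        d = np.linalg.norm(traj[w:] - traj[:-w], axis=1)
        dt = trace.times[w:] - trace.times[:-w]
        out[w:] = d / dt
    return out


def velocity_series(trace: MotionTrace, accelerometer: Accelerometer) -> np.ndarray:
    """(T, 3) backward-difference velocity; first ``window`` rows are NaN."""
    w = accelerometer.window
    traj = _resolve_series(accelerometer.attachment, trace)
    out = np.full((len(trace), 3), np.nan)
    if len(trace) > w:
        dt = (trace.times[w:] - trace.times[:-w])[:, None]
        out[w:] = (traj[w:] - traj[:-w]) / dt
    return out


# ---------------------------------------------------------------------------
# Control gestures
# ---------------------------------------------------------------------------

def detect_control_gesture(trace: MotionTrace, spec: GestureSpec) -> list[GadgetEvent]:
    """Fire a control event when the pose predicate holds for the dwell time.

    The event is stamped at hold-start + dwell; a release event follows when
    the predicate first breaks.  Separate holds give separate events.
    """
    held = np.array([bool(spec.predicate(p)) for p in trace.poses()])
    events: list[GadgetEvent] = []
    active = False
    start: float | None = None
    for t, h in zip(trace.times, held):
        if h:
            if start is None:
                start = float(t)
            if not active and t - start >= spec.dwell:
                events.append(GadgetEvent(float(start + spec.dwell), spec.name,
                                          "activated", spec.dwell))
                active = True
        else:
            if active:
                events.append(GadgetEvent(float(t), spec.name, "released",
                                          float(t - start)))
                active = False
            start = None
    return events


def suppression_mask(trace: MotionTrace, events: list[GadgetEvent]) -> np.ndarray:
    """(T,) boolean: True while a control gesture is held (between an
    activation and the following release) — frames on which exercise
    processing for the involved limb must be skipped."""
    mask = np.zeros(len(trace), dtype=bool)
    active_from: float | None = None
    for e in sorted(events, key=lambda e: e.time):
        if e.kind == "activated":
            active_from = e.time
        elif e.kind == "released" and active_from is not None:
            mask |= (trace.times >= active_from) & (trace.times < e.time)
            active_from = None
    if active_from is not None:
        mask |= trace.times >= active_from
    return mask
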