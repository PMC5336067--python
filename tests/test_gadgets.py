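import numpy as np
import pytest

from amplimotion.core_model import JointName, MotionTrace, default_rest_pose
from amplimotion.gadgets import (
    Accelerometer,
    GestureSpec,
    Rope,
    detect_control_gesture,
    events_from_lengths,
    rope_events,
    rope_length,
    rope_lengths,
    speed,
    speed_series,
    suppression_mask,
)


def _trace_with_hand_heights(heights):
    base = default_rest_pose().as_array()
    from amplimotion.core_model import JOINT_INDEX
    k = JOINT_INDEX[JointName.HAND_LEFT]
    pos = np.tile(base, (len(heights), 1, 1))
    pos[:, k, 2] = heights
    return MotionTrace(np.arange(len(heights)) / 30.0, pos)


def test_rope_length_between_joint_and_fixed_point():
    pose = default_rest_pose()
    anchor = pose[JointName.HAND_LEFT] + np.array([0.0, 0.0, 1.0])
    rope = Rope(JointName.HAND_LEFT, anchor, trigger_length=0.5)
    assert rope_length(pose, rope) == pytest.approx(1.0)


def test_rope_events_hand_counted_sequence():
    # lengths around trigger 1.0, hysteresis 0.1, above mode:
    lengths = np.array([0.5, 0.8, 1.05, 1.02, 0.95, 0.85, 1.2, 0.5])
    #         idx:       0    1     2     3     4     5    6    7
    # activation at 2 (>=1.0); 3 stays active; 4 within hysteresis (>=0.9)
    # still active; 5 releases (<0.9); 6 re-activates; 7 releases.
    times = np.arange(len(lengths)) / 30.0
    rope = Rope(np.zeros(3), np.array([1.0, 0, 0]), trigger_length=1.0,
                hysteresis=0.1)
    ev = events_from_lengths(times, lengths, rope)
    kinds = [(e.kind, round(e.time * 30)) for e in ev]
    assert kinds == [("activated", 2), ("released", 5),
                     ("activated", 6), ("released", 7)]


def test_rope_no_chatter_inside_hysteresis_band():
    lengths = np.array([1.05, 0.95, 1.05, 0.95, 1.05, 0.95])
    times = np.arange(len(lengths)) / 30.0
    rope = Rope(np.zeros(3), np.array([1.0, 0, 0]), trigger_length=1.0,
                hysteresis=0.1)
    ev = events_from_lengths(times, lengths, rope)
    assert [e.kind for e in ev] == ["activated"]  # single event, no chatter


def test_rope_below_mode_fires_on_approach():
    lengths = np.array([1.5, 1.2, 0.9, 0.95, 1.2])
    times = np.arange(len(lengths)) / 30.0
    rope = Rope(np.zeros(3), np.array([1.0, 0, 0]), trigger_length=1.0,
                hysteresis=0.1, mode="below")
    ev = events_from_lengths(times, lengths, rope)
    assert [(e.kind, round(e.time * 30)) for e in ev] == [
        ("activated", 2), ("released", 4)]


def test_rope_active_on_first_frame():
    heights = np.full(5, 2.0)
    trace = _trace_with_hand_heights(heights)
    anchor = np.array([0.0, 0.0, 10.0])
    rope = Rope(JointName.HAND_LEFT, anchor, trigger_length=9.0, mode="below")
    ev = rope_events(trace, rope)
    assert ev and ev[0].kind == "activated" and ev[0].time == 0.0


def test_events_strictly_alternate(rng):
    lengths = rng.uniform(0.5, 1.5, 300)
    times = np.arange(300) / 30.0
    rope = Rope(np.zeros(3), np.array([1.0, 0, 0]), trigger_length=1.0)
    ev = events_from_lengths(times, lengths, rope)
    for a, b in zip(ev, ev[1:]):
        assert a.kind != b.kind
        assert b.time > a.time


# ---------------------------------------------------------------------------
# Accelerometer
# ---------------------------------------------------------------------------

def test_speed_matches_hand_computation():
    heights = np.array([1.0, 1.0, 1.1, 1.3, 1.3])
    trace = _trace_with_hand_heights(heights)
    acc = Accelerometer(JointName.HAND_LEFT, window=2)
    # frame 3: |1.3 - 1.0| over 2/30 s = 4.5 m/s
    assert speed(trace, 3, acc) == pytest.approx(0.3 / (2 / 30.0))


def test_speed_undefined_before_window():
    trace = _trace_with_hand_heights(np.linspace(1, 2, 5))
    acc = Accelerometer(JointName.HAND_LEFT, window=2)
    with pytest.raises(ValueError):
        speed(trace, 1, acc)


def test_speed_series_nan_prefix_then_matches_scalar():
    trace = _trace_with_hand_heights(np.linspace(1.0, 2.0, 10))
    acc = Accelerometer(JointName.HAND_LEFT, window=3)
    s = speed_series(trace, acc)
    assert np.all(np.isnan(s[:3]))
    for i in range(3, 10):
        assert s[i] == pytest.approx(speed(trace, i, acc))


# ---------------------------------------------------------------------------
# Control gestures
# ---------------------------------------------------------------------------

def test_dwell_gesture_fires_after_hold_and_releases():
    heights = np.concatenate([np.full(10, 1.0), np.full(30, 2.0),
                              np.full(10, 1.0)])
    trace = _trace_with_hand_heights(heights)
    spec = GestureSpec(lambda p: p[JointName.HAND_LEFT][2] > 1.5,
                       dwell=0.5, name="raise")
    ev = detect_control_gesture(trace, spec)
    assert [e.kind for e in ev] == ["activated", "released"]
    hold_start = 10 / 30.0
    assert ev[0].time == pytest.approx(hold_start + 0.5)
    assert ev[1].time == pytest.approx(40 / 30.0)


def test_short_hold_below_dwell_fires_nothing():
    heights = np.concatenate([np.full(10, 1.0), np.full(10, 2.0),
                              np.full(10, 1.0)])
    trace = _trace_with_hand_heights(heights)
    spec = GestureSpec(lambda p: p[JointName.HAND_LEFT][2] > 1.5, dwell=0.5)
    assert detect_control_gesture(trace, spec) == []


def test_gesture_rejects_sub_half_second_dwell():
    with pytest.raises(ValueError):
        GestureSpec(lambda p: True, dwell=0.2)


def test_suppression_mask_covers_hold():
    heights = np.concatenate([np.full(10, 1.0), np.full(30, 2.0),
                              np.full(10, 1.0)])
    trace = _trace_with_hand_heights(heights)
    spec = GestureSpec(lambda p: p[JointName.HAND_LEFT][2] > 1.5, dwell=0.5)
    ev = detect_control_gesture(trace, spec)
    mask = suppression_mask(trace, ev)
    assert not mask[:25].any()          # before activation (10 + 15 frames)
    assert mask[25:40].all()            # active hold
    assert not mask[40:].any()          # after release
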