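import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amplimotion.amplifier import (
    AmplifierChain,
    amplify_chain,
    amplify_chain_iterative,
    amplify_direct,
    factors_to_restrictions,
    retarget_pose,
    retarget_trace,
)
from amplimotion.core_model import (
    JointName,
    MotionTrace,
    default_rest_pose,
    fit_skeleton_to_pose,
)
from amplimotion.synth_motion import PlayerParams, generate_exercise_trace


def test_amplify_direct_scales_displacement():
    resting = np.array([0.3, -0.1, 0.7])
    position = resting + np.array([0.02, -0.01, 0.05])
    factors = np.array([2.0, 3.0, 10.0])
    out = amplify_direct(resting, position, factors)
    np.testing.assert_allclose(out - resting, [0.04, -0.03, 0.5])


def test_amplify_direct_per_direction_factors():
    resting = np.zeros(3)
    f_pos = np.array([2.0, 2.0, 2.0])
    f_neg = np.array([5.0, 5.0, 5.0])
    up = amplify_direct(resting, np.array([0.1, 0.0, 0.0]), f_pos, f_neg)
    down = amplify_direct(resting, np.array([-0.1, 0.0, 0.0]), f_pos, f_neg)
    assert up[0] == pytest.approx(0.2)
    assert down[0] == pytest.approx(-0.5)


def test_amplify_direct_identity_at_rest():
    resting = np.array([0.1, 0.2, 0.3])
    out = amplify_direct(resting, resting, np.array([7.0, 7.0, 7.0]))
    np.testing.assert_array_equal(out, resting)


# ---------------------------------------------------------------------------
# Bone chain
# ---------------------------------------------------------------------------

@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10**6))
def test_chain_closed_form_equals_iterative_exactly(seed):
    rng = np.random.default_rng(seed)
    chain = AmplifierChain(f_res=rng.uniform(0.0, 1.0, 3))
    disp = rng.normal(0.0, 0.3, 3)
    closed = amplify_chain(chain, disp)
    iterative = amplify_chain_iterative(chain, disp)
    np.testing.assert_array_equal(closed, iterative)
    np.testing.assert_array_equal(closed, 25.0 * chain.f_res * disp)


def test_chain_full_restriction_gives_factor_25():
    chain = AmplifierChain(f_res=np.ones(3))
    out = amplify_chain_iterative(chain, np.array([1.0, 1.0, 1.0]))
    np.testing.assert_array_equal(out, [25.0, 25.0, 25.0])


def test_factors_to_restrictions_roundtrip():
    f = np.array([1.0, 12.5, 25.0])
    res = factors_to_restrictions(f)
    np.testing.assert_allclose(res * 25.0, f)
    assert np.all((0 < res) & (res <= 1))


def test_factors_to_restrictions_rejects_out_of_range():
    with pytest.raises(ValueError):
        factors_to_restrictions(np.array([26.0]))
    with pytest.raises(ValueError):
        factors_to_restrictions(np.array([0.0]))


def test_chain_rejects_restrictions_outside_unit_interval():
    with pytest.raises(ValueError):
        AmplifierChain(f_res=np.array([1.2, 0.5, 0.5]))


# ---------------------------------------------------------------------------
# Retargeting
# ---------------------------------------------------------------------------

def test_retarget_preserves_avatar_bone_lengths(profile, avatar, player_params):
    trace = generate_exercise_trace("climb", player_params, duration=5.0)
    avatar_trace, _ = retarget_trace(trace, profile, avatar)
    for parent, child in [(JointName.SHOULDER_LEFT, JointName.ELBOW_LEFT),
                          (JointName.ELBOW_LEFT, JointName.WRIST_LEFT),
                          (JointName.HIP_RIGHT, JointName.KNEE_RIGHT),
                          (JointName.KNEE_RIGHT, JointName.ANKLE_RIGHT)]:
        seg = avatar_trace.joint(child) - avatar_trace.joint(parent)
        lens = np.linalg.norm(seg, axis=1)
        np.testing.assert_allclose(lens, avatar.length(parent, child), atol=1e-6)


def test_retarget_hand_reaches_amplified_marker_when_reachable(profile, avatar,
                                                               player_params):
    trace = generate_exercise_trace("climb", player_params, duration=5.0)
    avatar_trace, markers = retarget_trace(trace, profile, avatar)
    target = markers["hand_left"]["amplified"]
    hand = avatar_trace.joint(JointName.HAND_LEFT)
    shoulder = avatar_trace.joint(JointName.SHOULDER_LEFT)
    reach = avatar.arm_length("left")
    dist = np.linalg.norm(target - shoulder, axis=1)
    # outside the annulus (too far, or too close for the folded arm) the
    # solver clamps; only genuinely reachable targets must be hit exactly
    reachable = (dist <= reach * 0.999) & (dist >= 0.3 * reach)
    err = np.linalg.norm(hand - target, axis=1)
    assert np.all(err[reachable] < 1e-6)


def test_retarget_trunk_copied_with_body_offset(profile, avatar, player_params):
    trace = generate_exercise_trace("climb", player_params, duration=2.0)
    avatar_trace, _ = retarget_trace(trace, profile, avatar)
    for j in (JointName.HIP_CENTER, JointName.HEAD, JointName.SPINE):
        np.testing.assert_allclose(
            avatar_trace.joint(j), trace.joint(j) + profile.body_offset,
            atol=1e-12)


def test_retarget_pose_matches_trace_path(profile, avatar, player_params):
    trace = generate_exercise_trace("climb", player_params, duration=1.0)
    avatar_trace, _ = retarget_trace(trace, profile, avatar)
    single = retarget_pose(trace.pose(10), profile, avatar)
    np.testing.assert_allclose(single.pose.as_array(), avatar_trace.positions[10],
                               atol=1e-9)


def test_retarget_missing_limb_warns_and_copies(profile, avatar, player_params):
    import dataclasses
    trimmed = dataclasses.replace(
        profile, limbs={k: v for k, v in profile.limbs.items() if k != "foot_left"})
    trace = generate_exercise_trace("climb", player_params, duration=1.0)
    with pytest.warns(UserWarning, match="foot_left"):
        avatar_trace, markers = retarget_trace(trace, trimmed, avatar)
    assert "foot_left" not in markers
    np.testing.assert_allclose(
        avatar_trace.joint(JointName.FOOT_LEFT),
        trace.joint(JointName.FOOT_LEFT) + trimmed.body_offset, atol=1e-12)
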