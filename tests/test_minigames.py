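import numpy as np
import pytest

from amplimotion.minigames import (
    BirdConfig,
    BirdState,
    BoatConfig,
    BoatState,
    LadderConfig,
    LadderState,
    MoleConfig,
    MoleState,
    Ring,
    count_ring_passes,
    default_ring_course,
    mole_schedule,
    run_session,
    segment_crosses_ring,
    step_bird,
    step_boat,
    step_ladder,
    step_mole,
    trunk_lean,
)
from amplimotion.synth_motion import PlayerParams, generate_exercise_trace

DT = 1.0 / 30.0


# ---------------------------------------------------------------------------
# Ladder
# ---------------------------------------------------------------------------

def _ladder_state(profile):
    return LadderState.from_profile(LadderConfig(), profile)


def _grab_point(state, hand):
    """A marker position well inside the hand's grab band."""
    rope = state.ropes[hand]
    return np.asarray(rope.end_b, float) - np.array([0.0, 0.0, rope.trigger_length * 0.99])


def _rest_point(state, hand, profile):
    lc = profile.limbs[hand]
    return lc.resting + lc.offset


def test_ladder_alternates_hands(profile):
    state = _ladder_state(profile)
    rest = {h: _rest_point(state, h, profile) for h in state.ropes}
    pose = dict(rest)
    # left grabs: counts; left grabs again (after leaving band): must NOT count
    step_ladder(state, {**pose, "hand_left": _grab_point(state, "hand_left")}, DT)
    assert state.rungs == 1 and state.active_hand == "hand_right"
    step_ladder(state, pose, DT)  # leave the band
    step_ladder(state, {**pose, "hand_left": _grab_point(state, "hand_left")}, DT)
    assert state.rungs == 1  # same hand twice: no progress
    step_ladder(state, pose, DT)
    step_ladder(state, {**pose, "hand_right": _grab_point(state, "hand_right")}, DT)
    assert state.rungs == 2 and state.active_hand == "hand_left"


def test_ladder_requires_band_reentry(profile):
    state = _ladder_state(profile)
    rest = {h: _rest_point(state, h, profile) for h in state.ropes}
    grab = {**rest, "hand_left": _grab_point(state, "hand_left")}
    step_ladder(state, grab, DT)
    for _ in range(10):  # holding inside the band must not re-count
        step_ladder(state, grab, DT)
    assert state.rungs == 1


def test_ladder_finishes_at_n_rungs(profile):
    cfg = LadderConfig(n_rungs=4)
    state = LadderState.from_profile(cfg, profile)
    rest = {h: _rest_point(state, h, profile) for h in state.ropes}
    hands = ["hand_left", "hand_right", "hand_left", "hand_right"]
    for h in hands:
        step_ladder(state, rest, DT)
        step_ladder(state, {**rest, h: _grab_point(state, h)}, DT)
    assert state.finished and state.rungs == 4


# ---------------------------------------------------------------------------
# Boat
# ---------------------------------------------------------------------------

def test_boat_stroke_requires_all_four_ropes(profile):
    state = BoatState.from_profile(BoatConfig(), profile)
    rest = {}
    for hand in ("hand_left", "hand_right"):
        lc = profile.limbs[hand]
        rest[hand] = lc.resting + lc.offset

    def reach(key):
        rope = state.ropes[key]
        hand = "hand_left" if key.startswith("left") else "hand_right"
        direction = np.asarray(rope.end_b) - rest[hand]
        direction /= np.linalg.norm(direction)
        return np.asarray(rope.end_b) - direction * rope.trigger_length * 0.99

    # only three of four: no stroke
    for key in ("left_fore", "left_aft", "right_fore"):
        hand = "hand_left" if key.startswith("left") else "hand_right"
        step_boat(state, {**rest, hand: reach(key)}, DT)
        step_boat(state, rest, DT)
    assert state.strokes == 0
    # fourth rope completes the stroke, order-free
    step_boat(state, {**rest, "hand_right": reach("right_aft")}, DT)
    assert state.strokes == 1
    assert state.fired == set()  # cleared for the next stroke


def test_boat_finishes_course(profile):
    cfg = BoatConfig(course_length=4.0, stroke_advance=2.0)
    state = BoatState.from_profile(cfg, profile)
    rest = {h: profile.limbs[h].resting + profile.limbs[h].offset
            for h in ("hand_left", "hand_right")}

    def reach(key):
        rope = state.ropes[key]
        hand = "hand_left" if key.startswith("left") else "hand_right"
        d = np.asarray(rope.end_b) - rest[hand]
        d /= np.linalg.norm(d)
        return np.asarray(rope.end_b) - d * rope.trigger_length * 0.99

    for _ in range(2):
        for key in state.ropes:
            hand = "hand_left" if key.startswith("left") else "hand_right"
            step_boat(state, {**rest, hand: reach(key)}, DT)
            step_boat(state, rest, DT)
    assert state.finished and state.strokes == 2


# ---------------------------------------------------------------------------
# Mole
# ---------------------------------------------------------------------------

def test_mole_schedule_deterministic_and_spaced():
    cfg = MoleConfig()
    s1 = mole_schedule(cfg, np.random.default_rng(5))
    s2 = mole_schedule(cfg, np.random.default_rng(5))
    assert s1 == s2
    times = [t for t, _ in s1]
    for a, b in zip(times, times[1:]):
        assert b - a == pytest.approx(cfg.visibility + cfg.gap)
    assert all(0 <= h < 4 for _, h in s1)
    assert all(t < cfg.duration for t in times)


def test_mole_hit_requires_speed_and_downward_strike(profile):
    cfg = MoleConfig()
    state = MoleState.from_profile(cfg, profile, np.random.default_rng(0))
    spawn_t, hole_i = state.schedule[0]
    hole = state.holes[hole_i]
    # advance to just after spawn
    while state.elapsed < spawn_t + DT:
        step_mole(state, {"hand_right": hole + 10.0}, np.zeros(3), DT)
    # in hole but too slow: no hit
    step_mole(state, {"hand_right": hole}, np.array([0.0, 0.0, -0.5]), DT)
    assert state.score == 0
    # in hole, fast but moving upward: no hit
    step_mole(state, {"hand_right": hole}, np.array([0.0, 0.0, 2.0]), DT)
    assert state.score == 0
    # fast downward strike inside the hole: hit
    step_mole(state, {"hand_right": hole}, np.array([0.0, 0.0, -2.0]), DT)
    assert state.score == 1
    # mole is gone: striking again cannot double-count
    step_mole(state, {"hand_right": hole}, np.array([0.0, 0.0, -2.0]), DT)
    assert state.score == 1


# ---------------------------------------------------------------------------
# Bird: dynamics and ring geometry
# ---------------------------------------------------------------------------

def test_bird_yaw_integrates_hand_difference():
    cfg = BirdConfig(rings=[])
    state = BirdState(cfg)
    for _ in range(30):  # 1 s with left hand 0.1 above right
        step_bird(state, 0.05, -0.05, 0.0, DT)
    assert state.yaw == pytest.approx(cfg.yaw_gain * 0.1, rel=1e-9)


def test_bird_level_flight_advances_straight():
    cfg = BirdConfig(rings=[])
    state = BirdState(cfg)
    for _ in range(30):
        step_bird(state, 0.0, 0.0, 0.0, DT)
    np.testing.assert_allclose(state.position,
                               cfg.start + [cfg.forward_speed, 0.0, 0.0],
                               atol=1e-9)


def test_bird_lean_back_climbs():
    cfg = BirdConfig(rings=[])
    state = BirdState(cfg)
    for _ in range(30):
        step_bird(state, 0.0, 0.0, -0.3, DT)  # lean back
    assert state.position[2] > cfg.start[2]


def test_trunk_lean_sign_convention():
    hip = np.array([0.0, 0.0, 1.0])
    assert trunk_lean(hip, hip + [0.1, 0.0, 0.5]) > 0   # forward (x) positive
    assert trunk_lean(hip, hip + [-0.1, 0.0, 0.5]) < 0
    assert trunk_lean(hip, hip + [0.0, 0.0, 0.5]) == pytest.approx(0.0)


def _brute_force_crossing(p0, p1, ring, n=20_000):
    """Dense sampling oracle: does the segment pierce the disc?"""
    ts = np.linspace(0.0, 1.0, n)
    pts = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    side = (pts - ring.center) @ ring.normal
    cross = np.where(np.diff(np.sign(side)) != 0)[0]
    for i in cross:
        mid = 0.5 * (pts[i] + pts[i + 1])
        if np.linalg.norm(mid - ring.center) <= ring.radius + 1e-4:
            return True
    return False


def test_segment_ring_crossing_matches_brute_force(rng):
    agree = 0
    for _ in range(100):
        ring = Ring(center=rng.normal(0, 2, 3),
                    normal=rng.normal(0, 1, 3),
                    radius=float(rng.uniform(0.5, 2.0)))
        p0 = rng.normal(0, 3, 3)
        p1 = rng.normal(0, 3, 3)
        got = segment_crosses_ring(p0, p1, ring)
        want = _brute_force_crossing(p0, p1, ring)
        assert got == want
        agree += 1
    assert agree == 100


def test_count_ring_passes_counts_each_ring_once():
    rings = [Ring(center=np.array([1.0, 0, 0]), normal=np.array([1.0, 0, 0]),
                  radius=1.0)]
    path = np.array([[0.0, 0, 0], [2.0, 0, 0], [0.5, 0, 0], [2.0, 0, 0]])
    assert count_ring_passes(path, rings) == 1


def test_default_ring_course_shape():
    rings = default_ring_course(6)
    assert len(rings) == 6
    xs = [r.center[0] for r in rings]
    assert xs == sorted(xs) and xs[0] > 0


# ---------------------------------------------------------------------------
# Session determinism
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("game,pattern", [("ladder", "climb"), ("boat", "row")])
def test_run_session_deterministic(game, pattern, profile, avatar, player_params):
    cfg = {"ladder": LadderConfig(), "boat": BoatConfig()}[game]
    trace = generate_exercise_trace(pattern, player_params, duration=20.0)
    r1 = run_session(game, cfg, trace, profile, avatar, seed=3)
    r2 = run_session(game, cfg, trace, profile, avatar, seed=3)
    assert r1.to_dict() == r2.to_dict()
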