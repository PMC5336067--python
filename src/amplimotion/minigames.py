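"""Deterministic state machines for the four mini-games.

All four games are driven by the amplified end-effector markers (plus the
raw trunk for the Paper-Bird) and produce a :class:`GameResult`:

* **Ladder** (climbing): alternate hands; a rung is scored when the active
  hand's rope to the next-rung grab point closes within a 5 % band of the
  calibrated amplified maximum raise.  Time to the top is the outcome.
* **Boat** (rowing): four ropes — fore and aft on each side; a stroke
  completes, advancing the boat, once all four have activated since the last
  stroke, in any order.  Time to the finish line is the outcome.
* **Whack-a-Mole** (hitting): 20 moles appear one at a time out of 4 holes on
  a seeded schedule within 120 s; a mole is hit when the hammer tip is inside
  the hole while moving downward at or above the minimum speed.  The score is
  the number of moles hit.
* **Paper-Bird** (flying): hand-height difference steers, trunk lean pitches;
  rings passed are counted by segment–disc intersection along the flight
  path.

Rung grab points and rowing anchors are placed on the movement axis two
metres beyond the calibrated range, so the rope length measures progress
along that axis and lateral jitter cannot mask a genuine maximal movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .amplifier import AmplifiedPose, retarget_trace
from .calibration import CalibrationProfile
from .core_model import JointName, MotionTrace, SkeletonModel
from .gadgets import Accelerometer, GadgetEvent, Rope, velocity_series

__all__ = [
    "LadderConfig", "BoatConfig", "MoleConfig", "BirdConfig", "Ring",
    "GameResult",
    "LadderState", "BoatState", "MoleState", "BirdState",
    "step_ladder", "step_boat", "step_mole", "step_bird",
    "mole_schedule", "default_hole_positions", "DEFAULT_HOLE_OFFSETS",
    "default_ring_course", "count_ring_passes",
    "segment_crosses_ring", "trunk_lean", "run_session",
]

ANCHOR_DISTANCE = 2.0  # m beyond the calibrated range; see module docstring


# ---------------------------------------------------------------------------
# Configurations and results
# ---------------------------------------------------------------------------

@dataclass
class LadderConfig:
    n_rungs: int = 10
    rung_spacing: float = 0.3   # m, scenery only: grab detection is range-based
    band: float = 0.05          # grab band as a fraction of the amplified range


@dataclass
class BoatConfig:
    course_length: float = 30.0       # m
    stroke_advance: float = 2.0       # m per completed stroke
    activation_fraction: float = 0.8  # fore/aft reach (fraction of range) to fire


@dataclass
class MoleConfig:
    n_moles: int = 20
    duration: float = 120.0
    hole_radius: float = 0.25
    min_hit_speed: float = 1.0   # m/s, downward strike gate
    visibility: float = 3.0      # s a mole stays out
    gap: float = 0.5             # s between moles
    holes: np.ndarray | None = None  # (4, 3); default: around the hammer hand


@dataclass
class Ring:
    center: np.ndarray
    radius: float
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)
        if self.radius <= 0:
            raise ValueError("ring radius must be positive")


@dataclass
class BirdConfig:
    forward_speed: float = 5.0   # m/s
    yaw_gain: float = 3.0        # rad/s per metre of hand-height difference
    pitch_gain: float = 1.0      # rad of flight pitch per rad of trunk lean
    max_pitch: float = 1.0       # rad, clamp
    start: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 10.0]))
    rings: list[Ring] = field(default_factory=list)


@dataclass
class GameResult:
    game: str
    subject: str
    elapsed_time: float
    score: int = 0
    rings_passed: int = 0
    completed: bool = False

    def to_dict(self) -> dict:
        return {"game": self.game, "subject": self.subject,
                "elapsed_time": self.elapsed_time, "score": self.score,
                "rings_passed": self.rings_passed, "completed": self.completed}


def _marker_points(pose) -> dict[str, np.ndarray]:
    """Accept an AmplifiedPose or a plain {limb: point} mapping."""
    if isinstance(pose, AmplifiedPose):
        return {limb: m.amplified for limb, m in pose.markers.items()}
    return pose


# ---------------------------------------------------------------------------
# Ladder
# ---------------------------------------------------------------------------

@dataclass
class LadderState:
    config: LadderConfig
    ropes: dict[str, Rope]          # per hand: rope to the next-rung grab point
    rungs: int = 0
    active_hand: str | None = None  # None: first grab decides; then alternate
    in_band: dict[str, bool] = field(default_factory=dict)
    elapsed: float = 0.0
    finished: bool = False
    events: list[GadgetEvent] = field(default_factory=list)

    @classmethod
    def from_profile(cls, config: LadderConfig, profile: CalibrationProfile) -> "LadderState":
        """Grab ropes anchored overhead at the calibrated amplified maximum."""
        ropes: dict[str, Rope] = {}
        for hand in ("hand_left", "hand_right"):
            lc = profile.limbs[hand]
            rng = float(lc.amplified_range_pos()[2])
            rest = lc.resting + lc.offset
            anchor = rest + np.array([0.0, 0.0, rng + ANCHOR_DISTANCE])
            ropes[hand] = Rope(
                end_a=hand, end_b=anchor,
                trigger_length=ANCHOR_DISTANCE + config.band * rng,
                hysteresis=config.band * rng,
                mode="below",
            )
        return cls(config=config, ropes=ropes,
                   in_band={"hand_left": False, "hand_right": False})


def _rope_len_to_point(rope: Rope, point: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(point, float) - np.asarray(rope.end_b, float)))


def step_ladder(state: LadderState, amplified_pose, dt: float) -> LadderState:
    """Advance the ladder one frame; mutates and returns the state."""
    if state.finished:
        return state
    state.elapsed += dt
    points = _marker_points(amplified_pose)
    for hand, rope in state.ropes.items():
        length = _rope_len_to_point(rope, points[hand])
        was = state.in_band[hand]
        if not was and length <= rope.trigger_length:
            state.in_band[hand] = True
            if state.active_hand is None or hand == state.active_hand:
                state.rungs += 1
                state.events.append(GadgetEvent(state.elapsed, f"rung_{hand}",
                                                "activated", length))
                state.active_hand = ("hand_right" if hand == "hand_left"
                                     else "hand_left")
                if state.rungs >= state.config.n_rungs:
                    state.finished = True
        elif was and length > rope.trigger_length + rope.hysteresis:
            state.in_band[hand] = False
    return state


# ---------------------------------------------------------------------------
# Boat
# ---------------------------------------------------------------------------

@dataclass
class BoatState:
    config: BoatConfig
    ropes: dict[str, Rope]   # keys: left_fore, left_aft, right_fore, right_aft
    in_state: dict[str, bool] = field(default_factory=dict)
    fired: set = field(default_factory=set)
    distance: float = 0.0
    elapsed: float = 0.0
    strokes: int = 0
    finished: bool = False
    events: list[GadgetEvent] = field(default_factory=list)

    @classmethod
    def from_profile(cls, config: BoatConfig, profile: CalibrationProfile) -> "BoatState":
        ropes: dict[str, Rope] = {}
        for side, hand in (("left", "hand_left"), ("right", "hand_right")):
            lc = profile.limbs[hand]
            rest = lc.resting + lc.offset
            for direction, rng in (("fore", float(lc.amplified_range_pos()[0])),
                                   ("aft", float(lc.amplified_range_neg()[0]))):
                sgn = 1.0 if direction == "fore" else -1.0
                anchor = rest + np.array([sgn * (rng + ANCHOR_DISTANCE), 0.0, 0.0])
                trigger = ANCHOR_DISTANCE + (1.0 - config.activation_fraction) * rng
                ropes[f"{side}_{direction}"] = Rope(
                    end_a=hand, end_b=anchor, trigger_length=trigger,
                    hysteresis=0.1 * rng if rng > 0 else 0.01, mode="below",
                )
        return cls(config=config, ropes=ropes,
                   in_state={k: False for k in ropes})


def step_boat(state: BoatState, amplified_pose, dt: float) -> BoatState:
    if state.finished:
        return state
    state.elapsed += dt
    points = _marker_points(amplified_pose)
    for key, rope in state.ropes.items():
        hand = "hand_left" if key.startswith("left") else "hand_right"
        length = _rope_len_to_point(rope, points[hand])
        was = state.in_state[key]
        if not was and length <= rope.trigger_length:
            state.in_state[key] = True
            state.fired.add(key)
            state.events.append(GadgetEvent(state.elapsed, key, "activated", length))
        elif was and length > rope.trigger_length + rope.hysteresis:
            state.in_state[key] = False
    if state.fired >= set(state.ropes):
        state.strokes += 1
        state.distance += state.config.stroke_advance
        state.fired.clear()
        if state.distance >= state.config.course_length:
            state.finished = True
    return state


# ---------------------------------------------------------------------------
# Whack-a-Mole
# ---------------------------------------------------------------------------

# Avatar-space hole displacements from the hammer hand's rest marker.
DEFAULT_HOLE_OFFSETS = np.array([
    [0.30, -0.25, -0.45],
    [0.30, 0.25, -0.45],
    [0.50, 0.00, -0.45],
    [0.10, 0.00, -0.45],
])


def default_hole_positions(hammer_rest: np.ndarray) -> np.ndarray:
    """Four holes in front of and around the hammer hand's resting point,
    at strikeable depth (within the amplified movement box)."""
    return np.asarray(hammer_rest, dtype=float) + DEFAULT_HOLE_OFFSETS


def default_ring_course(n_rings: int = 5, spacing: float = 30.0,
                        radius: float = 2.5,
                        start: np.ndarray | None = None) -> list[Ring]:
    """A gently weaving line of rings ahead of the bird's start point."""
    start = np.array([0.0, 0.0, 10.0]) if start is None else np.asarray(start, float)
    rings = []
    for i in range(n_rings):
        lateral = 6.0 * np.sin(0.9 * (i + 1))
        vertical = 3.0 * np.sin(0.5 * (i + 1))
        center = start + np.array([(i + 1) * spacing, lateral, vertical])
        rings.append(Ring(center=center, radius=radius, normal=[1.0, 0.0, 0.0]))
    return rings


def mole_schedule(config: MoleConfig, rng: np.random.Generator
                  ) -> list[tuple[float, int]]:
    """Seeded spawn schedule: (spawn_time, hole index) for each mole.

    One mole at a time, uniform hole choice, fixed visibility window and gap,
    truncated at the game duration.
    """
    schedule: list[tuple[float, int]] = []
    t = 0.0
    for _ in range(config.n_moles):
        if t >= config.duration:
            break
        schedule.append((t, int(rng.integers(4))))
        t += config.visibility + config.gap
    return schedule


@dataclass
class MoleState:
    config: MoleConfig
    schedule: list[tuple[float, int]]
    holes: np.ndarray
    hammer: Accelerometer = field(default_factory=lambda: Accelerometer(JointName.HAND_RIGHT))
    idx: int = 0              # next/current mole in the schedule
    active: bool = False
    hit_current: bool = False
    score: int = 0
    elapsed: float = 0.0
    finished: bool = False
    events: list[GadgetEvent] = field(default_factory=list)

    @classmethod
    def from_profile(cls, config: MoleConfig, profile: CalibrationProfile,
                     rng: np.random.Generator) -> "MoleState":
        lc = profile.limbs["hand_right"]
        holes = (config.holes if config.holes is not None
                 else default_hole_positions(lc.resting + lc.offset))
        return cls(config=config, schedule=mole_schedule(config, rng), holes=holes)


def step_mole(state: MoleState, amplified_pose, velocity: np.ndarray,
              dt: float) -> MoleState:
    """Advance one frame.  ``velocity`` is the hammer tip's backward-difference
    velocity (m/s) at this frame (NaN allowed on the first frames)."""
    if state.finished:
        return state
    state.elapsed += dt
    cfg = state.config
    if state.elapsed >= cfg.duration or state.idx >= len(state.schedule):
        state.finished = True
        return state

    spawn_t, hole_i = state.schedule[state.idx]
    if not state.active:
        if state.elapsed >= spawn_t and not state.hit_current:
            state.active = True
    if state.active and state.elapsed > spawn_t + cfg.visibility:
        state.active = False
        state.idx += 1
        state.hit_current = False
        return state

    if state.active:
        points = _marker_points(amplified_pose)
        tip = points["hand_right"]
        vz = velocity[2]
        spd = float(np.linalg.norm(velocity))
        in_hole = np.linalg.norm(tip - state.holes[hole_i]) <= cfg.hole_radius
        if in_hole and np.isfinite(spd) and spd >= cfg.min_hit_speed and vz < 0:
            state.score += 1
            state.events.append(GadgetEvent(state.elapsed, f"mole_{state.idx}",
                                            "activated", spd))
            state.active = False
            state.idx += 1
    return state


# ---------------------------------------------------------------------------
# Paper-Bird
# ---------------------------------------------------------------------------

def trunk_lean(hip_center: np.ndarray, shoulder_center: np.ndarray) -> float:
    """Signed sagittal trunk angle from vertical (rad); forward lean positive."""
    d = np.asarray(shoulder_center, float) - np.asarray(hip_center, float)
    return float(np.arctan2(d[0], d[2]))


def segment_crosses_ring(p0: np.ndarray, p1: np.ndarray, ring: Ring) -> bool:
    """Does the segment p0→p1 pass through the ring's disc?"""
    s0 = float(np.dot(p0 - ring.center, ring.normal))
    s1 = float(np.dot(p1 - ring.center, ring.normal))
    if s0 * s1 > 0 or s0 == s1:
        return False
    q = p0 + (s0 / (s0 - s1)) * (p1 - p0)
    return float(np.linalg.norm(q - ring.center)) <= ring.radius


def count_ring_passes(path: np.ndarray, rings: Sequence[Ring]) -> int:
    """Rings crossed by a polyline path, each counted at most once."""
    path = np.asarray(path, dtype=float)
    passed = 0
    for ring in rings:
        for i in range(len(path) - 1):
            if segment_crosses_ring(path[i], path[i + 1], ring):
                passed += 1
                break
    return passed


@dataclass
class BirdState:
    config: BirdConfig
    position: np.ndarray = None
    yaw: float = 0.0  # rad from +x toward -y (positive = right turn)
    elapsed: float = 0.0
    rings_passed: set = field(default_factory=set)
    path: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.position is None:
            self.position = self.config.start.astype(float).copy()
        self.path.append(self.position.copy())


def step_bird(state: BirdState, z_left: float, z_right: float,
              lean: float, dt: float) -> BirdState:
    """One integration step of the flight model.

    ``z_left − z_right < 0`` (left hand lower) turns left; forward trunk lean
    pitches the bird down, leaning back pitches it up.
    """
    cfg = state.config
    state.yaw += cfg.yaw_gain * (z_left - z_right) * dt
    pitch = float(np.clip(-cfg.pitch_gain * lean, -cfg.max_pitch, cfg.max_pitch))
    v = cfg.forward_speed * np.array([
        np.cos(pitch) * np.cos(state.yaw),
        -np.cos(pitch) * np.sin(state.yaw),
        np.sin(pitch),
    ])
    new_pos = state.position + v * dt
    for i, ring in enumerate(cfg.rings):
        if i not in state.rings_passed and segment_crosses_ring(
                state.position, new_pos, ring):
            state.rings_passed.add(i)
    state.position = new_pos
    state.path.append(new_pos.copy())
    state.elapsed += dt
    return state


# ---------------------------------------------------------------------------
# Session loop
# ---------------------------------------------------------------------------

def _limb_marker_series(trace: MotionTrace, profile: CalibrationProfile,
                        avatar_model: SkeletonModel,
                        amplify: bool) -> dict[str, np.ndarray]:
    """(T, 3) end-effector marker per limb: amplified, or offset-shifted raw."""
    if amplify:
        _, markers = retarget_trace(trace, profile, avatar_model)
        return {limb: m["amplified"] for limb, m in markers.items()}
    from .calibration import LIMB_JOINTS
    return {limb: trace.joint(joint) + profile.limbs[limb].offset
            for limb, joint in LIMB_JOINTS.items() if limb in profile.limbs}


def run_session(game: str, config, trace: MotionTrace,
                profile: CalibrationProfile, avatar_model: SkeletonModel,
                seed: int = 0, amplify: bool = True,
                subject: str = "subject") -> GameResult:
    """Play one full game session on a motion trace.

    Deterministic for fixed (trace, config, seed).  ``amplify=False`` replays
    the identical game with the amplifier bypassed (raw, offset-shifted
    movement) — the ablation arm.
    """
    markers = _limb_marker_series(trace, profile, avatar_model, amplify)
    times = trace.times
    dts = np.diff(times, prepend=times[0] - 1.0 / trace.frame_rate)

    if game == "ladder":
        state = LadderState.from_profile(config, profile)
        for i in range(len(trace)):
            step_ladder(state, {limb: m[i] for limb, m in markers.items()}, dts[i])
            if state.finished:
                break
        elapsed = state.elapsed if state.finished else trace.duration
        return GameResult("ladder", subject, float(elapsed),
                          score=state.rungs, completed=state.finished)

    if game == "boat":
        state = BoatState.from_profile(config, profile)
        for i in range(len(trace)):
            step_boat(state, {limb: m[i] for limb, m in markers.items()}, dts[i])
            if state.finished:
                break
        elapsed = state.elapsed if state.finished else trace.duration
        return GameResult("boat", subject, float(elapsed),
                          score=state.strokes, completed=state.finished)

    if game == "mole":
        rng = np.random.default_rng(seed)
        state = MoleState.from_profile(config, profile, rng)
        hammer = markers["hand_right"]
        vel = np.full((len(trace), 3), np.nan)
        w = state.hammer.window
        if len(trace) > w:
            vel[w:] = (hammer[w:] - hammer[:-w]) / (times[w:] - times[:-w])[:, None]
        for i in range(len(trace)):
            step_mole(state, {"hand_right": hammer[i]}, vel[i], dts[i])
            if state.finished:
                break
        elapsed = min(trace.duration, config.duration)
        completed = state.finished or state.elapsed >= config.duration
        return GameResult("mole", subject, float(elapsed),
                          score=state.score, completed=completed)

    if game == "bird":
        state = BirdState(config)
        zl = markers["hand_left"][:, 2]
        zr = markers["hand_right"][:, 2]
        hip = trace.joint(JointName.HIP_CENTER)
        sho = trace.joint(JointName.SHOULDER_CENTER)
        for i in range(len(trace)):
            lean = trunk_lean(hip[i], sho[i])
            step_bird(state, float(zl[i]), float(zr[i]), lean, dts[i])
        return GameResult("bird", subject, float(trace.duration),
                          rings_passed=len(state.rings_passed), completed=True)

    raise ValueError(f"unknown game {game!r}")
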