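"""Seeded synthetic players: impaired and unimpaired motion traces.

No public motion dataset exists for the capture setup this toolkit targets,
so every pipeline stage is exercised against generated traces that emulate a
30 Hz consumer depth sensor:

* per-joint Gaussian jitter ("scattering"),
* reduced movement amplitude for impaired players (``amplitude_scale s``:
  an ``s = 0.2`` player moves a fifth of the full range — the hand-only,
  arms-resting pattern of severe muscle weakness),
* seated resting postures (wheelchair users) vs standing control players,
* minimum-jerk interpolation between key poses, the standard smooth profile
  of voluntary reaching movements.

All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_model import (
    JOINT_INDEX,
    JOINTS,
    JointName,
    MotionTrace,
    SkeletonPose,
    default_rest_pose,
    default_skeleton_model,
)
from .minigames import BirdConfig, BirdState, MoleConfig, mole_schedule, step_bird

__all__ = [
    "PlayerParams",
    "generate_calibration_trace",
    "generate_exercise_trace",
    "generate_cohort",
    "CohortMember",
    "ParamsDistribution",
    "seated_rest_pose",
    "scripted_whack_plan",
    "fly_session_trace",
    "FULL_ARM_RANGE",
]

FRAME_RATE = 30.0
# Full-range hand excursion of the nominal body: the arm's reach.
FULL_ARM_RANGE = float(default_skeleton_model().arm_length("left"))
FULL_LEG_RANGE = float(default_skeleton_model().leg_length("left"))


@dataclass
class PlayerParams:
    """One synthetic player.

    ``amplitude_scale`` s ∈ (0, 1]: fraction of the full range the player can
    move; ``cadence``: repetitions per second during exercise; ``jitter_sd``:
    per-joint, per-axis Gaussian sensor noise; ``reaction_time``: delay before
    responding to a cue; ``aim_sd``: end-point precision of targeted strikes
    (user space); ``row_style``: "straight" or "diagonal" (the circular,
    sideways-drifting stroke some players fall back to).
    """

    amplitude_scale: float = 1.0
    cadence: float = 1.0
    jitter_sd: float = 0.005
    seated: bool = False
    reaction_time: float = 0.3
    aim_sd: float = 0.0
    row_style: str = "straight"
    row_amplitude: float = 1.0   # stroke extent as a fraction of own range
    fly_duration: float = 120.0  # s a player keeps flying (no goal, no limit)
    fly_control_sd: float = 0.02  # steering noise of the flight controls
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.amplitude_scale <= 1:
            raise ValueError("amplitude_scale must be in (0, 1]")
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")


def seated_rest_pose(timestamp: float = 0.0) -> SkeletonPose:
    """Wheelchair resting posture: trunk lowered, legs bent, hands on the lap."""
    pose = default_rest_pose(timestamp=timestamp)
    p = {j: pose[j].copy() for j in JOINTS}
    drop = np.array([0.0, 0.0, -0.40])  # pelvis at chair height
    for j in (JointName.HIP_CENTER, JointName.SPINE, JointName.SHOULDER_CENTER,
              JointName.HEAD, JointName.SHOULDER_LEFT, JointName.SHOULDER_RIGHT,
              JointName.HIP_LEFT, JointName.HIP_RIGHT):
        p[j] = p[j] + drop
    for side, sgn in (("LEFT", 1.0), ("RIGHT", -1.0)):
        y = sgn * 0.09
        p[JointName[f"KNEE_{side}"]] = np.array([0.40, y, 0.55])
        p[JointName[f"ANKLE_{side}"]] = np.array([0.42, y, 0.17])
        p[JointName[f"FOOT_{side}"]] = np.array([0.54, y, 0.10])
        ys = sgn * 0.18
        p[JointName[f"ELBOW_{side}"]] = np.array([0.08, ys + sgn * 0.02, 0.78])
        p[JointName[f"WRIST_{side}"]] = np.array([0.20, ys - sgn * 0.04, 0.68])
        p[JointName[f"HAND_{side}"]] = np.array([0.27, ys - sgn * 0.06, 0.66])
    return SkeletonPose(timestamp, p)


def _rest_pose(params: PlayerParams) -> SkeletonPose:
    return seated_rest_pose() if params.seated else default_rest_pose()


def _minjerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _assemble(frames: np.ndarray, params: PlayerParams,
              rng: np.random.Generator) -> MotionTrace:
    """Add sensor jitter and wrap (T, 20, 3) frames into a trace."""
    if params.jitter_sd > 0:
        frames = frames + rng.normal(0.0, params.jitter_sd, size=frames.shape)
    times = np.arange(frames.shape[0]) / FRAME_RATE
    return MotionTrace(times, frames, frame_rate=FRAME_RATE)


def _pulse(t: np.ndarray, start: float, rise: float, hold: float,
           fall: float) -> np.ndarray:
    """0→1→0 min-jerk pulse: rise, hold at 1, fall."""
    out = np.zeros_like(t)
    up = (t >= start) & (t < start + rise)
    out[up] = _minjerk((t[up] - start) / rise)
    hold_m = (t >= start + rise) & (t < start + rise + hold)
    out[hold_m] = 1.0
    down = (t >= start + rise + hold) & (t < start + rise + hold + fall)
    out[down] = 1.0 - _minjerk((t[down] - start - rise - hold) / fall)
    return out


_HAND_JOINTS = {"left": JointName.HAND_LEFT, "right": JointName.HAND_RIGHT}
_FOOT_JOINTS = {"left": JointName.FOOT_LEFT, "right": JointName.FOOT_RIGHT}


# ---------------------------------------------------------------------------
# Calibration trace
# ---------------------------------------------------------------------------

def generate_calibration_trace(params: PlayerParams,
                               rest_seconds: float = 5.0) -> MotionTrace:
    """Rest, then per-axis maximal excursions of every tracked limb.

    Both hands (then both feet) are stretched to ``s × full range`` along
    each axis and direction in turn, holding the maximal stretch for three
    seconds — the calibration instruction is "stretch as far as possible and
    hold", and the hold is what lets the range estimator average sensor
    jitter down at the peak (a fleeting extremum is unrecoverable once the
    jitter is comparable to the movement itself: for a severely restricted
    user the 5 mm sensor jitter is a sixth of the whole movement range).
    The resting phase is longer than any hold so that the stillest window of
    the trace always lies inside genuine rest rather than on a held stretch.
    """
    s = params.amplitude_scale
    rest = _rest_pose(params)
    base = rest.as_array()

    move = 3.8  # s per excursion: 0.4 out, 3.0 hold, 0.4 back
    n_moves = 2 * 3 * 2  # (hands, feet) x axes x directions
    total = rest_seconds + n_moves * move
    n = int(round(total * FRAME_RATE)) + 1
    t = np.arange(n) / FRAME_RATE

    frames = np.tile(base, (n, 1, 1))
    start = rest_seconds
    for joints, amplitude in ((_HAND_JOINTS, s * FULL_ARM_RANGE),
                              (_FOOT_JOINTS, s * FULL_LEG_RANGE)):
        for axis in range(3):
            for sgn in (1.0, -1.0):
                pulse = _pulse(t, start, 0.4, 3.0, 0.4)
                for j in joints.values():
                    frames[:, JOINT_INDEX[j], axis] += sgn * amplitude * pulse
                start += move
    rng = np.random.default_rng(params.seed)
    return _assemble(frames, params, rng)


# ---------------------------------------------------------------------------
# Exercise traces
# ---------------------------------------------------------------------------

def generate_exercise_trace(pattern: str, params: PlayerParams,
                            duration: float, **kwargs) -> MotionTrace:
    """Kinematically plausible joint stream for one exercise.

    Patterns: ``climb`` (alternating maximal hand raises at the cadence),
    ``row`` (bilateral fore-aft ellipses; optional diagonal style), ``whack``
    (reactive strikes toward cued holes; pass ``plan=`` a list of
    ``(cue_time, user-space displacement)``), ``fly`` (hand-height /
    trunk-lean schedule; pass ``controls=`` (T, 2) of height-difference and
    lean, or use the default gentle weave).
    """
    generators = {"climb": _gen_climb, "row": _gen_row,
                  "whack": _gen_whack, "fly": _gen_fly}
    if pattern not in generators:
        raise ValueError(f"unknown pattern {pattern!r}; expected one of {sorted(generators)}")
    return generators[pattern](params, duration, **kwargs)


def _base_frames(params: PlayerParams, duration: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    n = int(round(duration * FRAME_RATE)) + 1
    t = np.arange(n) / FRAME_RATE
    base = _rest_pose(params).as_array()
    return t, np.tile(base, (n, 1, 1))


def _gen_climb(params: PlayerParams, duration: float) -> MotionTrace:
    """Alternating hand raises to the player's own maximum at the cadence."""
    s = params.amplitude_scale
    t, frames = _base_frames(params, duration)
    period = 1.0 / params.cadence
    amp = s * FULL_ARM_RANGE
    k = 0
    start = 0.0
    while start < duration:
        hand = _HAND_JOINTS["left" if k % 2 == 0 else "right"]
        pulse = _pulse(t, start, 0.4 * period, 0.1 * period, 0.4 * period)
        frames[:, JOINT_INDEX[hand], 2] += amp * pulse
        k += 1
        start += period
    rng = np.random.default_rng(params.seed + 1)
    return _assemble(frames, params, rng)


def _gen_row(params: PlayerParams, duration: float) -> MotionTrace:
    """Bilateral fore-aft stroke ellipses; 'diagonal' style adds the sideways
    circular drift seen in players who cannot row straight."""
    s = params.amplitude_scale
    t, frames = _base_frames(params, duration)
    w = 2 * np.pi * params.cadence
    amp_x = params.row_amplitude * s * FULL_ARM_RANGE
    amp_z = 0.15 * s * FULL_ARM_RANGE
    x = amp_x * np.sin(w * t)
    z = amp_z * np.cos(w * t)
    y = np.zeros_like(t)
    if params.row_style == "diagonal":
        y = 0.5 * amp_x * np.sin(w * t)         # sideways drift, in phase
        z = 0.3 * amp_x * np.abs(np.cos(w * t))  # circular lift
    for hand, sgn in ((JointName.HAND_LEFT, 1.0), (JointName.HAND_RIGHT, -1.0)):
        frames[:, JOINT_INDEX[hand], 0] += x
        frames[:, JOINT_INDEX[hand], 1] += sgn * y
        frames[:, JOINT_INDEX[hand], 2] += z
    rng = np.random.default_rng(params.seed + 2)
    return _assemble(frames, params, rng)


def _gen_whack(params: PlayerParams, duration: float,
               plan: list[tuple[float, np.ndarray]] | None = None) -> MotionTrace:
    """Reactive strikes: after each cue + reaction time, raise, then strike
    fast and downward onto the cued point, hold briefly, return to rest.

    ``plan``: (cue_time, user-space displacement of the strike point from the
    right hand's rest).  Aim error ``aim_sd`` perturbs each strike endpoint.
    """
    t, frames = _base_frames(params, duration)
    rng = np.random.default_rng(params.seed + 3)
    hand = JOINT_INDEX[JointName.HAND_RIGHT]
    if plan is None:
        plan = []
    raise_h = 0.35 * params.amplitude_scale * FULL_ARM_RANGE
    for cue_t, disp in plan:
        disp = np.asarray(disp, dtype=float)
        if params.aim_sd > 0:
            disp = disp + rng.normal(0.0, params.aim_sd, size=3)
        t0 = cue_t + params.reaction_time
        # Reach a hover point above the target (0.35 s), strike down fast
        # (0.15 s), hold in the hole (0.15 s), return to rest (0.3 s).  The
        # hover and strike pulses fall back together, so the hand returns to
        # rest smoothly.
        above = disp + np.array([0.0, 0.0, raise_h])
        hover = _pulse(t, t0, 0.35, 0.30, 0.3)
        strike = _pulse(t, t0 + 0.35, 0.15, 0.15, 0.3)
        frames[:, hand, :] += (hover[:, None] * above
                               + strike[:, None] * (disp - above))
    return _assemble(frames, params, rng)


def _gen_fly(params: PlayerParams, duration: float,
             controls: np.ndarray | None = None) -> MotionTrace:
    """Hand-height and trunk-lean schedule for the flying game.

    ``controls``: (T, 2) array of desired (z_left − z_right, trunk lean) in
    user displacement space; default is a gentle sinusoidal weave.
    """
    s = params.amplitude_scale
    t, frames = _base_frames(params, duration)
    if controls is None:
        diff = 0.3 * s * FULL_ARM_RANGE * np.sin(2 * np.pi * 0.1 * t)
        lean = 0.1 * np.sin(2 * np.pi * 0.05 * t)
        controls = np.column_stack([diff, lean])
    controls = np.asarray(controls, dtype=float)
    if controls.shape != (len(t), 2):
        raise ValueError(f"controls must be ({len(t)}, 2)")
    _apply_fly_controls(frames, controls)
    rng = np.random.default_rng(params.seed + 4)
    return _assemble(frames, params, rng)


def _apply_fly_controls(frames: np.ndarray, controls: np.ndarray) -> None:
    """In place: hand-height split and trunk lean (rotate the shoulder girdle
    and head about the hip centre in the sagittal plane)."""
    half = controls[:, 0] / 2.0
    frames[:, JOINT_INDEX[JointName.HAND_LEFT], 2] += half
    frames[:, JOINT_INDEX[JointName.HAND_RIGHT], 2] -= half
    hip = frames[:, JOINT_INDEX[JointName.HIP_CENTER], :]
    for j in (JointName.SHOULDER_CENTER, JointName.HEAD, JointName.SPINE,
              JointName.SHOULDER_LEFT, JointName.SHOULDER_RIGHT):
        rel = frames[:, JOINT_INDEX[j], :] - hip
        r = np.linalg.norm(rel[:, [0, 2]], axis=1)
        ang0 = np.arctan2(rel[:, 0], rel[:, 2])
        ang = ang0 + controls[:, 1]
        rel[:, 0] = r * np.sin(ang)
        rel[:, 2] = r * np.cos(ang)
        frames[:, JOINT_INDEX[j], :] = hip + rel


# ---------------------------------------------------------------------------
# Scripted (closed-loop) players
# ---------------------------------------------------------------------------

def scripted_whack_plan(config: MoleConfig, seed: int,
                        amplitude_scale: float,
                        hole_displacements: np.ndarray) -> list[tuple[float, np.ndarray]]:
    """Strike plan for a player who knows the mole schedule.

    ``hole_displacements``: (4, 3) avatar-space displacements of the holes
    from the hammer hand's rest marker.  A calibrated player's user-space
    displacement is the avatar displacement scaled by ``s`` (the calibration
    maps their maximum onto the avatar's full range).
    """
    schedule = mole_schedule(config, np.random.default_rng(seed))
    return [(spawn_t, amplitude_scale * hole_displacements[hole])
            for spawn_t, hole in schedule]


def _pursuit_command(config: BirdConfig, position: np.ndarray, yaw: float,
                     rings_passed: set, pursuit_gain: float
                     ) -> tuple[float, float]:
    """Avatar-space (hand-height difference, trunk lean) steering toward the
    first unpassed ring; level flight once the course is done."""
    for i, ring in enumerate(config.rings):
        if i not in rings_passed and ring.center[0] > position[0]:
            to_ring = ring.center - position
            desired_yaw = float(np.arctan2(-to_ring[1], to_ring[0]))
            yaw_err = (desired_yaw - yaw + np.pi) % (2 * np.pi) - np.pi
            dist = max(float(np.linalg.norm(to_ring[[0, 1]])), 1e-6)
            desired_pitch = float(np.arctan2(to_ring[2], dist))
            diff = float(np.clip(pursuit_gain * yaw_err / config.yaw_gain,
                                 -0.4, 0.4))
            lean = float(np.clip(-desired_pitch / config.pitch_gain, -0.5, 0.5))
            return diff, lean
    return 0.0, 0.0


def fly_session_trace(config: BirdConfig, profile, params: PlayerParams,
                      pursuit_gain: float = 1.5) -> MotionTrace:
    """Closed-loop flying player: a trace whose replay threads the rings.

    A real player steers by watching the screen, so the flight loop must be
    closed over what the game actually measures — the *amplified* hand
    markers and the sensed trunk lean, jitter included.  Each frame the
    player issues a pursuit command toward the next ring based on the flight
    state they perceived ``reaction_time`` seconds ago (a first-order lag
    additionally models limited hand speed; ``fly_control_sd`` models
    steering imprecision in the player's own range), the frame is rendered
    and jittered, the game-side signals are read back off that frame, and
    the simulated flight advances before the next command.  Replaying the
    returned trace through a game session reproduces this flight exactly.
    """
    from .amplifier import _amplified_target
    from .minigames import trunk_lean

    s = params.amplitude_scale
    duration = params.fly_duration
    n = int(round(duration * FRAME_RATE)) + 1
    dt = 1.0 / FRAME_RATE
    rng = np.random.default_rng(params.seed + 4)
    jitter = (rng.normal(0.0, params.jitter_sd, size=(n, len(JOINTS), 3))
              if params.jitter_sd > 0 else np.zeros((n, len(JOINTS), 3)))
    base = _rest_pose(params).as_array()
    lc_l = profile.limbs["hand_left"]
    lc_r = profile.limbs["hand_right"]
    i_hl, i_hr = JOINT_INDEX[JointName.HAND_LEFT], JOINT_INDEX[JointName.HAND_RIGHT]
    i_hip, i_sc = JOINT_INDEX[JointName.HIP_CENTER], JOINT_INDEX[JointName.SHOULDER_CENTER]

    state = BirdState(config)
    frames = np.empty((n, len(JOINTS), 3))
    alpha = dt / (0.2 + dt)  # 0.2 s hand-movement lag
    delay = max(0, int(round(params.reaction_time * FRAME_RATE)))
    seen: list[tuple[np.ndarray, float]] = []  # perceived (position, yaw)
    cmd_diff, cmd_lean = 0.0, 0.0
    for i in range(n):
        seen.append((state.position.copy(), state.yaw))
        pos_seen, yaw_seen = seen[max(0, i - delay)]
        want_diff, want_lean = _pursuit_command(config, pos_seen, yaw_seen,
                                                state.rings_passed, pursuit_gain)
        if params.fly_control_sd > 0:
            want_diff += rng.normal(0.0, params.fly_control_sd)
            want_lean += rng.normal(0.0, params.fly_control_sd)
        cmd_diff += alpha * (want_diff - cmd_diff)
        cmd_lean += alpha * (want_lean - cmd_lean)

        frame = base.copy()[None]
        # The player realises the command within their own range (scaled by s);
        # calibration maps it back onto the avatar scale.
        _apply_fly_controls(frame, np.array([[s * cmd_diff, cmd_lean]]))
        frame = frame[0] + jitter[i]
        frames[i] = frame

        zl = _amplified_target(frame[i_hl], lc_l)[2]
        zr = _amplified_target(frame[i_hr], lc_r)[2]
        lean_meas = trunk_lean(frame[i_hip], frame[i_sc])
        step_bird(state, zl, zr, lean_meas, dt)

    times = np.arange(n) / FRAME_RATE
    return MotionTrace(times, frames, frame_rate=FRAME_RATE)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortMember:
    subject: str
    group: str  # "control" | "target"
    params: PlayerParams


@dataclass
class ParamsDistribution:
    """Uniform sampling ranges for per-subject parameters."""

    s_range: tuple[float, float] = (0.9, 1.0)
    cadence: float = 1.0
    jitter_sd: float = 0.005
    seated: bool = False
    reaction_range: tuple[float, float] = (0.2, 0.4)
    aim_sd: float = 0.02
    row_amplitude_range: tuple[float, float] = (0.95, 1.0)
    diagonal_fraction: float = 0.0
    fly_duration_range: tuple[float, float] = (90.0, 160.0)
    fly_control_sd: float = 0.02

    def draw(self, rng: np.random.Generator, seed: int) -> PlayerParams:
        style = "diagonal" if rng.uniform() < self.diagonal_fraction else "straight"
        return PlayerParams(
            amplitude_scale=float(rng.uniform(*self.s_range)),
            cadence=self.cadence,
            jitter_sd=self.jitter_sd,
            seated=self.seated,
            reaction_time=float(rng.uniform(*self.reaction_range)),
            aim_sd=self.aim_sd,
            row_style=style,
            row_amplitude=float(rng.uniform(*self.row_amplitude_range)),
            fly_duration=float(rng.uniform(*self.fly_duration_range)),
            fly_control_sd=self.fly_control_sd,
            seed=seed,
        )


CONTROL_DEFAULTS = ParamsDistribution()
TARGET_DEFAULTS = ParamsDistribution(
    s_range=(0.05, 0.5),
    seated=True,
    reaction_range=(0.4, 1.0),
    aim_sd=0.02,  # same hand steadiness; amplification magnifies it
    row_amplitude_range=(0.7, 1.0),
    diagonal_fraction=0.25,
    fly_duration_range=(150.0, 260.0),  # no goal: motivated players fly longer
    fly_control_sd=0.08,
)


def generate_cohort(n_per_group: int, seed: int,
                    control_dist: ParamsDistribution | None = None,
                    target_dist: ParamsDistribution | None = None
                    ) -> list[CohortMember]:
    """Draw a balanced two-group cohort of synthetic players (seeded)."""
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    control_dist = control_dist or CONTROL_DEFAULTS
    target_dist = target_dist or TARGET_DEFAULTS
    rng = np.random.default_rng(seed)
    members: list[CohortMember] = []
    for group, dist in (("control", control_dist), ("target", target_dist)):
        for i in range(n_per_group):
            sub_seed = int(rng.integers(2**31 - 1))
            members.append(CohortMember(
                subject=f"{group}_{i + 1}", group=group,
                params=dist.draw(rng, sub_seed)))
    return members
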