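# Methods

This document records the model, the estimators, the default parameters
(with units), the scope of the synthetic-motion generators, the numerical
choices, and the known limitations of `amplimotion`.

## 1. Skeleton and motion model

The skeleton is the 20-joint consumer depth-sensor layout (hip/spine/
shoulder-centre/head trunk, shoulder–elbow–wrist–hand arms,
hip–knee–ankle–foot legs). All positions are metres in a right-handed
world frame with `z` up; time is seconds; the nominal frame rate is 30 Hz
(timestamps must be strictly increasing, uniform to 1 ms).

A `SkeletonModel` stores bone lengths; `fit_model` estimates them from a
trace (median inter-joint distance), `forward_place` poses the model.
Intermediate limb joints are placed by **closed-form two-bone inverse
kinematics** (law of cosines): target distances are clamped to the annulus
`[|L1 − L2|, L1 + L2]`, the bend direction comes from a per-limb hint vector
projected out of the shoulder→target axis, and solved segment lengths equal
the model's bone lengths to 1e−9 relative. Unreachable and inner-annulus
targets are clamped, never extrapolated.

## 2. Calibration

Calibration consumes a recording with a resting phase followed by maximal
per-axis stretches of both hands and both feet.

**Resting point** — per-axis median of the limb position over the stillest
window (minimum summed speed). Two robustness measures matter when genuine
movement is small relative to sensor jitter:

* speed is measured on a 0.5 s moving-average copy of the trajectory — raw
  frame-to-frame "speed" of white 5 mm jitter is ≈ 0.35 m/s, far above a
  restricted user's real movement, so window selection on raw speed is
  effectively random;
* the default window used by `calibrate` is 4 s — deliberately *longer* than
  any held stretch in the protocol (3 s), so a held maximum can never be the
  "stillest" window.

**Ranges** — per axis and per direction, the sustained maximum displacement
from rest: a Hampel despike (window 5 frames, 3 robust standard deviations;
replaces 1–2-frame sensor teleports by the local median and touches nothing
else), then the maximum of a 2.5 s rolling mean. Averaging, not an extremum
of raw frames, is essential: extremum estimators carry a bias of order one
jitter standard deviation (5 mm — a sixth of a severely restricted user's
entire 30 mm range). Measured performance of the range estimator under 5 mm
white jitter: bias ≈ 0.3 mm, sd ≈ 0.6 mm. Plateaus held ≥ 2.5 s pass
through exactly in noiseless data.

**Factors** — `F = avatar_required_range / user_range` per axis and
direction, clipped to `[1, 25]`; the avatar's required range is its arm (or
leg) length, derived from the avatar model, not hard-coded. Axes with under
1 cm of usable range are flagged unusable with factor 1. The per-limb
offset maps the user's resting point onto the avatar's rest pose (so a
seated player's lap-resting hand drives a standing avatar's hanging hand),
and a body offset relocates the unamplified trunk.

Parameter recovery, validated over 30 seeds × amplitude scales
{0.05, 0.1, 0.2, 0.5, 1.0} with 5 mm jitter: worst factor error 9.0%
relative, mean 1.9%.

## 3. Amplification and retargeting

Displacement-space amplification: `p' = offset + F ∘ (p − rest)`, with
separate factors per direction of each axis. The equivalent in-engine
construction is a chain of 25 nested bones, each copying its parent's
movement scaled by a restriction factor `f_res ∈ [0, 1]`; the end of the
chain moves by `25 · f_res` times the input. `amplify_chain` (closed form)
and `amplify_chain_iterative` (the 25-step parent-copy recurrence) agree
**bit-exactly**: the iterative oracle accumulates the 25-fold sum with
`math.fsum` (correctly rounded), which equals the single multiplication
`25 * f_res` for every double — naive left-to-right addition differs in the
last ulp for ~76% of random inputs.

`retarget_trace` amplifies the four end effectors, applies IK for elbows
and knees, and copies the trunk with the body offset. Bone lengths of the
avatar are preserved by construction.

## 4. Gadgets

* **Rope**: virtual elastic band between two attachment points (joints,
  markers, or fixed world points). Fires `activated` when its length
  crosses the trigger length (above-mode for stretch detection, below-mode
  for clap/reach detection), `released` only after re-crossing by a
  hysteresis band (default 10% of trigger length — millimetre jitter would
  otherwise chatter). Events strictly alternate; the first frame is
  evaluated directly against the threshold.
* **Accelerometer**: reports instantaneous speed of a point via backward
  differences over a configurable window.
* **Dwell gestures**: a predicate (e.g., hand within a radius of the head)
  held continuously for a dwell time fires a menu event and suppresses
  exercise processing for the involved limb while held.

## 5. Mini-games

All games run through `run_session(game, config, trace, profile, avatar,
amplify=, seed=)`, are fully deterministic given (trace, config, seed), and
score on *amplified* avatar markers — that is the mechanism being studied.

* **Ladder**: alternating-hand grabs; a grab counts when the active hand's
  rope to the next overhead anchor enters the 95–100% band of that hand's
  calibrated amplified maximum. Design note: the hand–anchor rope (fixed
  world point, below-mode) replaces a shoulder–hand rope because the
  shoulder–hand distance is non-monotonic in raise height (it equals arm
  length both hanging and fully overhead).
* **Boat**: four ropes (two per arm, fore/aft); a stroke completes when all
  four have fired, advancing the boat; finish the course or time out
  (120 s).
* **Whack-a-mole**: a seeded schedule of moles over 9 holes; a hit requires
  the hand marker inside the hole radius, downward motion, and speed above
  the threshold.
* **Paper-bird**: yaw integrates the amplified hand-height difference
  (`yaw += gain · (z_left − z_right) · dt`), pitch follows trunk lean;
  score is rings crossed, detected by exact segment–disc intersection.

## 6. Synthetic players and cohorts

Generators emulate a 30 Hz consumer depth sensor: white per-joint Gaussian
jitter (default 5 mm), amplitude scale `s ∈ (0, 1]` (fraction of full
reach the player can move), optional seated pose, cadence, reaction time,
aim noise, and steering noise. All are deterministic per seed.

* **Calibration pattern**: ≥ 5 s rest, then per-axis excursions with
  min-jerk transitions and a 3 s hold at each maximum. The hold length is a
  protocol requirement, not a convenience: with 5 mm jitter on a 30 mm
  range, the peak level is only estimable because ~90 frames sample it.
* **Exercise patterns**: `climb`, `row`, `whack` (strikes toward cued holes
  with reaction delay and aim noise), `fly`.
* **Closed-loop flight**: the paper-bird player is simulated closed-loop
  (`fly_session_trace`): each frame the generator reads back the *amplified*
  markers and sensed trunk lean (jitter included), steps the flight model,
  and steers toward the next ring using the state perceived `reaction_time`
  seconds ago, with first-order command lag and steering noise. Open-loop
  replay is structurally impossible here: yaw is an integrator, so a
  sub-millimetre bias in the sensed hand-height difference grows into
  metres of lateral error. Replaying the generated trace through
  `run_session` reproduces the flight bit-exactly.
* **Cohorts**: `generate_cohort(n, seed)` draws per-subject parameters from
  fixed group priors (control: `s ~ U(0.9, 1)`, standing; target:
  `s ~ U(0.05, 0.5)`, seated, longer reaction times), matched cadence.

## 7. Statistics

Long-format outcomes (`subject, group, metric, value`) are compared per
metric with: pooled two-sample t (raw samples or summary statistics
`mean, sd, n` — both paths agree to 1e−12), one-way ANOVA (`F = t²` to
1e−9 on ordinary samples), mean-centred Levene for variance equality
(flagging p ∈ (0.05, 0.10] as "weak"), and Kruskal–Wallis via the
chi-square approximation as a distribution-free corroboration. The group
verdict is "different" iff the t-test's two-sided p < 0.05; the type-I
error of the full pipeline is 5% ± 2% under the null (1000 seeded
replicates). Critical values (t ≈ 1.76 one-tailed, F ≈ 4.6 at df (1, 14))
come from scipy's distributions.

## 8. Numerical choices

* CSV/JSONL parsing uses pandas' round-trip float precision so stream
  round-trips are bit-exact.
* BVH I/O is hand-written (reader: full hierarchy + rotation-channel
  forward kinematics; writer: per-joint translation channels for exact
  position round-trips).
* `math.fsum` in the chain oracle (see §3).
* The internal `F = t²` consistency assert inside report generation uses a
  1e−6 *relative* tolerance: degenerate near-constant groups (an ablation
  arm where every subject times out at exactly 120 s) produce F ~ 4e8 where
  scipy's ANOVA and t² legitimately differ by ~2e−9 relative.

## 9. Limitations

* The skeleton is positions-only; joint orientations are not modelled, and
  the BVH writer exports translations rather than rotations.
* Sensor jitter is modelled as white Gaussian noise plus rare teleports;
  real depth sensors also show occlusion dropouts and temporally correlated
  error, which are not simulated.
* Synthetic players are simplified control models, not biomechanics: the
  equalisation findings are properties of the amplification mechanism under
  these models, not clinical claims.
* Calibration assumes the protocol's rest-then-hold structure; free-form
  recordings without held maxima will under-estimate ranges (by design —
  a fleeting extremum under jitter is not trustworthy).
* Amplification is per-axis linear with a hard [1, 25] clip; no non-linear
  response curves.
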