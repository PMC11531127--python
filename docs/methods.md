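# Methods

## Scope and model

`vgait` implements the control core of a walker-assisted virtual
walking task: a per-frame trigger state machine, the
acceleration-to-stride control law, the Hermite-curve feedback
geometry with its step score, and the trial outcome metrics, driven
either by recorded kinematic traces or by a synthetic-user simulator.
Rendering, avatar inverse kinematics, tracker/IMU drivers and
balance-board physics are deliberately outside the package: the
engine consumes scalar positions and one acceleration channel per
frame and emits events, geometry and numbers.

Conventions: SI units throughout (metres, m/s², seconds, degrees);
+x is anteroposterior (direction of progression), +y lateral, +z up.
The nominal frame rate is 90 Hz; the trace reader tolerates timing
jitter (warning above 20 % of the nominal interval) because event
detection is driven by sample values, not by assumed spacing.

## Controller constants and participant scaling

| constant | default | meaning |
|---|---|---|
| `a_max` | 0.4 m/s² | thrust peak at which the stride saturates |
| `a_min` | 0.1 m/s² | smallest thrust peak that triggers a step |
| `hip_disp_min` | 0.02 m | minimum forward hip travel during a thrust |
| `weight_shift_tol` | 0.15 m | lateral pelvis-to-leading-foot tolerance |
| `sl_avg_frac` | 0.7774 | healthy-adult stride length as a fraction of body height |
| `sl_max_factor` | 1.5 | `SL_max / SL_opt` |
| `trunk_factor_lo/hi` | 15° / 90° | posture bounds of the trunk factor and object length |

`SL_opt = ½ · sl_avg_frac · BH` (half the healthy average, because
exoskeleton users take shorter steps), `SL_max = 1.5 · SL_opt`, and
`SL_min = (a_min/a_max) · SL_max` — the stride commanded exactly at
the trigger threshold. The weight-shift tolerance is a length: the
pelvis center must come within 0.15 m laterally of the leading foot,
inclusive at the boundary.

## Trigger state machine

Phases IDLE → WALKER_READY → SHIFTED → THRUSTING encode the three
movements. WALKER_READY requires room for at least a minimal step
(`walker_x − trailing_x ≥ SL_min`); once latched it persists until a
step commits. The shift must hold on every frame from the start of
the thrust to its commit — one frame of lost shift aborts the cycle.
THRUSTING begins on a rising edge of the acceleration through
`a_min`: the channel must cross from below, so an aborted thrust
cannot re-arm inside the same burst of acceleration. A thrust commits
when the acceleration falls back below `a_min`, or immediately when
its running maximum reaches `a_max` (the commanded stride can grow no
further). At commit, the window maximum is `a_peak`, and the hip
displacement is measured from the pelvis position at the rising edge;
commits with less than 2 cm of travel are discarded as accidental
spikes (the controller returns to SHIFTED and waits for a fresh
edge). The concurrent fill cue tracks the running maximum while the
thrust is still in progress.

A committed stride longer than the walker-to-trailing-leg distance is
a collision: the event is recorded with `collided=True`, no foot
moves, and — like any commit — the controller returns to IDLE. Foot
labels (leading/trailing) are recomputed after every step; an exact
anteroposterior tie keeps the previous label to avoid chatter, and
labels are frozen during a thrust.

Numerical choices: all boundary comparisons follow the control law's
printed inequalities (`≥ a_min` strict `< a_max` on the linear
branch; both branches agree at `a_max`, so the boundary is
continuous); the collision test is strict (`SL >` room), so a step
landing exactly at the walker is legal.

## Feedback curve and score

The fusiform object's outline is a piecewise cubic Hermite curve with
zero tangents at the four keyframes. With zero tangents every segment
reduces to the smoothstep blend `y_a(2t³−3t²+1) + y_b(−2t³+3t²)`,
which the package evaluates in closed form; the test suite checks it
densely against a generic cubic-Hermite evaluator. When the feet are
far apart the target may exceed `SL_max`; the K3 abscissa is then
clamped to 0.99 so the knots stay strictly ordered (the curve shape
near the clamp is the only thing affected, and only in a stance no
legal step can produce). Evaluation outside [0, 1] is an error rather
than an extrapolation: scores are only computed for emitted steps,
whose strides lie in `[SL_min, SL_max]` by construction.

The step score multiplies the stride score (25–100, maximum exactly
on target) by the trunk factor (1–10, linear between 90° and 15°).
The trunk inclination entering the score is the value at the trigger
frame; the continuous per-frame inclination drives the object length
(2.0 m to 0.3 m over the same posture range). Inclination is the
angle between the pelvis-to-head segment and the calibrated vertical.

## Outcome metrics

Per trial: `n_steps` counts non-collided events; mean trunk
inclination averages the per-frame angle over the whole trial (every
frame, not per-step snapshots); stride deviation is the mean of
`100·|SL − SL_target|/SL_target` over completed steps, with the
target captured inside each event (it varies with the stance at
trigger time). A trial without a single completed step has an
*undefined* deviation, propagated as a missing value, never as 0.

## Synthetic user

The generator emulates one cycle per `cycle_period` (default 6 s, so
a 120 s trial holds 20 attempts): a walker push during the first 15 %
of the cycle, a first-order lateral shift (τ = 0.3 s) onto the
leading foot from 20 %, and a raised-cosine thrust starting at 55 %.
The thrust profile is renormalized after sampling so its discrete
maximum equals the intended peak exactly; the pelvis integrates the
profile, so the displacement gate sees physically consistent travel.
The thrust lasts 1.6 s (0.4·period for short cycles): long enough
that the gentlest on-target thrust — the first step, whose target is
`SL_opt/2` with the feet together — accrues more than 2 cm within the
supra-threshold window where the controller measures displacement.

Skill is three dials: the sd of the achieved peak around its aim
(`thrust_sd`; with `thrust_mean=None` the agent aims at the
acceleration that commands the current target stride), white lateral
noise (`shift_noise_sd`), and the per-cycle probability of holding
the shift through the thrust (`shift_hold_reliability`; a failed
cycle drops the shift mid-thrust until the burst ends). Trunk posture
is an AR(1) wobble (pole 0.9) around `trunk_mean` with stationary sd
`trunk_sd`. Defaults (`thrust_sd=0.04`, `shift_noise_sd=0.01`,
`reliability=0.9`, `trunk_mean=25°`, `trunk_sd=5°`) describe a
moderately practiced user: most cycles succeed, strides scatter
around target by roughly 10 %. A `LearningSchedule` drifts
`thrust_sd`, reliability and `trunk_mean` exponentially toward an
asymptote across trials, and `simulate_experiment` runs the
baseline / five-training-trials / retention design.

What the generator does *not* model: balance dynamics, vertical foot
trajectories, fatigue, reaction to the visual feedback, or any
coupling between posture and thrust quality. Passing tests therefore
demonstrate that the engine's laws and plumbing are correct and
internally consistent — not that human users behave like the agents.

## Problem sizes and determinism

Everything is seeded through `numpy.random.default_rng`; identical
(skill, seed) pairs give byte-identical trace CSVs, and the pipeline
is a pure function of (config, seed). The validation suite uses 100
random 18 s traces for the state-machine/offline-oracle equivalence
check, 200 replicates per skill level of 30 s trials for the
stochastic-monotonicity check of the outcome metrics, and 5001-point
grids for the curve comparisons; these sizes give stable medians and
dense coverage while keeping the full suite around half a minute.

## Known limitations

- Foot positions travel in the trace; there is no inverse-kinematics
  reconstruction, so recorded hardware sessions would need their own
  preprocessing to this format.
- The trunk inclination entering the score is sampled at the trigger
  frame; averaging over the step would give slightly different scores
  for wobbly postures.
- After a commit the controller only requires that room remain ahead
  of the trailing foot; it does not demand a fresh walker push when
  the previous push left enough space.
- A thrust whose running peak saturates `a_max` very early can be
  discarded by the displacement gate and, because re-arming needs a
  fresh rising edge, yield no step for that burst.
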