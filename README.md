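# vgait

A desk-scale Python implementation of the control engine behind an
immersive-VR virtual walking task for walker-assisted gait training —
the kind of task used to teach people the movement sequence that
triggers steps in a wearable exoskeleton. The package contains the
step-trigger state machine, the acceleration-to-stride control law,
the Hermite-curve feedback geometry and step score, the trial outcome
metrics, and a synthetic-user generator that produces 90 Hz kinematic
traces, so the whole engine can be exercised and validated without any
VR hardware.

## The task and its control laws

A user stands at a 4-wheeled walker and triggers virtual steps by
performing three movements in strict order:

1. **Walker advance** — push the walker forward to create room for the
   step;
2. **Weight shift** — move the pelvis laterally over the leading foot
   (within a 0.15 m tolerance) and hold it;
3. **Hip thrust** — accelerate the pelvis forward. The peak
   anteroposterior acceleration `a_peak` of the thrust commands the
   stride length:

```
SL = (a_peak / a_max) · SL_max    if a_min ≤ a_peak < a_max and hip displacement ≥ 2 cm
SL = SL_max                       if a_peak ≥ a_max and hip displacement ≥ 2 cm
SL = 0                            otherwise
```

with `a_max = 0.4 m/s²`, `a_min = 0.1 m/s²`. Stride lengths scale with
body height `BH`: the optimal stride is `SL_opt = ½ · 0.7774 · BH`
(half the average healthy-adult stride), `SL_max = 1.5 · SL_opt`, and
the per-step target is `SL_target = ½·SL_opt + |x_lead − x_trail|`.
Stepping exactly on target converges to strides of `SL_opt`.

Concurrent feedback is a spindle-shaped floor object whose outline is
a piecewise cubic Hermite curve with zero-tangent keyframes
`K1=(0,0)`, `K2=(SL_min/SL_max,0)`, `K3=(SL_target/SL_max,1)`,
`K4=(1,0)` over the normalized stride axis. Each committed step earns
a terminal score

```
Score = SL_score · trunk_factor,     SL_score = 75 · H(SL/SL_max) + 25
```

where `trunk_factor` falls linearly from 10 (trunk inclination ≤ 15°)
to 1 (≥ 90°), so the score spans 25–1000 points. Trial outcomes are
the number of completed steps, the frame-averaged trunk inclination,
and the mean absolute percent deviation of stride from target.

## Worked example

Simulate a 60 s trial of a moderately skilled synthetic user (1.75 m
tall, default controller constants) and compute its metrics:

```
$ vgait simulate --config examples/demo.yaml --out-dir out
n_steps=10 mean_trunk_inclination=24.70 deviation_from_target=9.68
```

The agent completed 10 virtual steps, held an average trunk
inclination of 24.7° (mild lean on the walker), and its strides missed
their targets by 9.7 % on average. `out/` now holds the full 90 Hz
trace (`trace.csv`), one JSON object per step with its score
(`results.jsonl`), and the one-row `metrics.csv`. The first recorded
step,

```
{"t_trigger": 4.41, "a_peak": 0.146, "stride_length": 0.371,
 "target_at_trigger": 0.340, ..., "sl_score": 99.5,
 "trunk_factor": 8.39, "score": 835.1}
```

shows the engine at work: a gentle 0.146 m/s² thrust commanded a
0.371 m stride against a 0.340 m target (the first step's target is
`SL_opt/2` because the feet start together), worth 835 of 1000 points.
Re-running the controller over the written trace reproduces the same
events (`vgait run out/trace.csv`), and the same seed reproduces the
same files byte for byte.

The same machinery is scriptable: `vgait.simulate_trial` returns a
typed trial record, `vgait.simulate_experiment` runs a
baseline/training/retention cohort design, and every controller
operation (`commanded_stride_length`, `build_curve`, `score_step`,
…) is a plain function.

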