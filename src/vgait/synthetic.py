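"""Synthetic user: 90 Hz kinematic traces of walker/shift/thrust cycles.

The generator emulates a person standing at a 4-wheeled walker and
triggering virtual steps: each cycle the agent pushes the walker
forward, shifts the pelvis laterally over the leading foot, holds the
shift, and produces a smooth forward hip thrust whose peak
acceleration it tries to place at the value that commands the target
stride length.  Skill is parameterized by the spread of the achieved
thrust peak, lateral pelvis noise, and the probability of holding the
weight shift through the whole thrust; a learning schedule drifts
those parameters across trials toward an asymptote.

The traces contain only what the trigger controller reads — scalar
anteroposterior/lateral/vertical coordinates, no joint kinematics or
balance dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .metrics import TrialRecord, compute_metrics
from .scaling import ControllerConstants, ParticipantModel, target_stride_length
from .trigger import AvatarFeet, KinematicSample, StepController

__all__ = [
    "AgentSkill",
    "LearningSchedule",
    "generate_thrust_profile",
    "simulate_trial",
    "simulate_experiment",
    "DEFAULT_RATE_HZ",
]

DEFAULT_RATE_HZ = 90.0
_THRUST_FRACTION_START = 0.55  # of the cycle period
_STANCE_HALF_WIDTH = 0.2  # m; lateral foot offset from the sagittal plane
_SHIFT_TAU = 0.3  # s; first-order time constant of the lateral shift
_TORSO_LENGTH = 0.7  # m; pelvis-to-head segment length
_PELVIS_HEIGHT = 1.0  # m
_TRUNK_AR = 0.9  # AR(1) pole of the trunk-inclination wobble


@dataclass(frozen=True)
class AgentSkill:
    """Behavioural parameters of one simulated user.

    ``thrust_mean=None`` means the agent aims its nominal thrust peak
    at the acceleration that commands the current target stride
    (skilled aiming); a float fixes the nominal peak instead.
    ``thrust_sd`` is the cycle-to-cycle spread of the achieved peak —
    the main "skill" dial.  ``shift_hold_reliability`` is the
    probability of holding the weight shift through a whole thrust.
    """

    thrust_mean: Optional[float] = None
    thrust_sd: float = 0.04
    shift_noise_sd: float = 0.01
    shift_hold_reliability: float = 0.9
    walker_advance: Optional[float] = None  # None: always leave full SL_max room
    cycle_period: float = 6.0
    trunk_mean: float = 25.0
    trunk_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thrust_sd < 0 or self.shift_noise_sd < 0 or self.trunk_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.shift_hold_reliability <= 1.0:
            raise ValueError("shift_hold_reliability must be a probability")
        if self.cycle_period < 1.0:
            raise ValueError("cycle_period must be at least 1 s")


@dataclass(frozen=True)
class LearningSchedule:
    """Exponential approach of skill parameters to an asymptote.

    At trial index k the drifting parameters take the value
    ``final + (initial - final) * exp(-rate * k)``; everything else is
    inherited from ``initial``.
    """

    initial: AgentSkill
    thrust_sd_final: float
    shift_reliability_final: float
    trunk_mean_final: float
    rate: float = 0.5  # per trial

    def skill_at(self, trial_index: int) -> AgentSkill:
        f = math.exp(-self.rate * trial_index)

        def blend(a: float, b: float) -> float:
            return b + (a - b) * f

        return replace(
            self.initial,
            thrust_sd=max(0.0, blend(self.initial.thrust_sd, self.thrust_sd_final)),
            shift_hold_reliability=min(
                1.0,
                max(
                    0.0,
                    blend(
                        self.initial.shift_hold_reliability,
                        self.shift_reliability_final,
                    ),
                ),
            ),
            trunk_mean=blend(self.initial.trunk_mean, self.trunk_mean_final),
        )


def generate_thrust_profile(
    peak: float, duration: float, rate: float = DEFAULT_RATE_HZ
) -> np.ndarray:
    """Raised-cosine acceleration burst whose sampled maximum equals
    ``peak`` exactly (the profile is renormalized after sampling)."""
    if peak < 0:
        raise ValueError("peak must be non-negative")
    n = max(2, int(round(duration * rate)) + 1)
    t = np.linspace(0.0, duration, n)
    raw = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / duration))
    if peak == 0.0:
        return np.zeros(n)
    return raw * (peak / raw.max())


def simulate_trial(
    skill: AgentSkill,
    duration: float,
    participant: ParticipantModel,
    constants: ControllerConstants | None = None,
    rate: float = DEFAULT_RATE_HZ,
) -> TrialRecord:
    """Simulate one trial and run the trigger controller over it.

    Deterministic given ``skill.seed``.  The returned record carries
    the full kinematic trace, the per-frame avatar feet (as seen by
    the controller at the start of each frame) and all emitted step
    events.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    constants = constants or ControllerConstants()
    rng = np.random.default_rng(skill.seed)
    dt = 1.0 / rate
    n = int(round(duration * rate))
    period = skill.cycle_period
    thrust_dur = min(1.6, 0.4 * period)

    feet0 = AvatarFeet(
        left_x=0.0,
        right_x=0.0,
        left_y=_STANCE_HALF_WIDTH,
        right_y=-_STANCE_HALF_WIDTH,
        leading="left",
    )
    ctrl = StepController(participant=participant, feet=feet0, constants=constants)

    # trunk wobble: AR(1) about trunk_mean with stationary sd trunk_sd
    innov_sd = skill.trunk_sd * math.sqrt(1.0 - _TRUNK_AR**2)
    trunk_dev = 0.0

    pelvis_x = 0.0
    pelvis_y = 0.0
    vel_x = 0.0
    walker_x = feet0.trailing_x + 0.5 * participant.sl_min  # no room yet
    walker_target = walker_x
    walker_rate = 0.0

    # per-cycle plan
    cycle_idx = -1
    accel_plan = np.zeros(0)
    accel_i0 = 0
    shift_target_y = 0.0
    release_frames: set[int] = set()

    samples: list[KinematicSample] = []
    feet_trace: list[AvatarFeet] = []

    for i in range(n):
        t = i * dt
        k = int(t // period)
        tc = t - k * period
        if k != cycle_idx:
            cycle_idx = k
            feet = ctrl.feet
            # walker plan: ramp to the new position over the first 15% of the cycle
            if skill.walker_advance is None:
                walker_target = max(walker_x, feet.trailing_x + participant.sl_max)
            else:
                walker_target = walker_x + skill.walker_advance
            walker_rate = (walker_target - walker_x) / max(0.15 * period, dt)
            # shift plan: aim the pelvis at the current leading foot
            shift_target_y = feet.leading_y
            # thrust plan
            target = target_stride_length(
                participant.sl_opt, feet.leading_x, feet.trailing_x
            )
            if skill.thrust_mean is None:
                nominal = constants.a_max * min(target / participant.sl_max, 1.0)
            else:
                nominal = skill.thrust_mean
            peak = nominal + (rng.normal(0.0, skill.thrust_sd) if skill.thrust_sd else 0.0)
            peak = max(0.0, peak)
            accel_plan = generate_thrust_profile(peak, thrust_dur, rate)
            accel_i0 = i + int(round((_THRUST_FRACTION_START * period - tc) * rate))
            release_frames = set()
            if rng.random() > skill.shift_hold_reliability:
                # drop the weight shift mid-thrust and stay off-balance
                # until the thrust is over, aborting this cycle's step
                r0 = accel_i0 + len(accel_plan) // 2
                release_frames = set(range(r0, accel_i0 + len(accel_plan) + 4))

        # walker ramp
        if walker_x < walker_target:
            walker_x = min(walker_target, walker_x + walker_rate * dt)

        # lateral shift: first-order approach (starts after the walker push)
        if tc >= 0.2 * period:
            pelvis_y += (shift_target_y - pelvis_y) * (1.0 - math.exp(-dt / _SHIFT_TAU))
        if skill.shift_noise_sd:
            pelvis_y_obs = pelvis_y + rng.normal(0.0, skill.shift_noise_sd)
        else:
            pelvis_y_obs = pelvis_y
        if i in release_frames:
            pelvis_y_obs = shift_target_y + 2.0 * constants.weight_shift_tol

        # thrust acceleration and pelvis forward motion
        j = i - accel_i0
        if 0 <= j < len(accel_plan):
            a = float(accel_plan[j])
            vel_x += a * dt
            pelvis_x += vel_x * dt
        else:
            a = 0.0
            vel_x = 0.0  # the agent settles between thrusts

        # trunk inclination
        trunk_dev = _TRUNK_AR * trunk_dev + (
            rng.normal(0.0, innov_sd) if skill.trunk_sd else 0.0
        )
        theta = math.radians(max(0.0, skill.trunk_mean + trunk_dev))

        sample = KinematicSample(
            t=t,
            pelvis_x=pelvis_x,
            pelvis_y=pelvis_y_obs,
            pelvis_z=_PELVIS_HEIGHT,
            head_x=pelvis_x + _TORSO_LENGTH * math.sin(theta),
            head_y=pelvis_y_obs,
            head_z=_PELVIS_HEIGHT + _TORSO_LENGTH * math.cos(theta),
            walker_x=walker_x,
            accel_x=a,
        )
        feet_trace.append(ctrl.feet)
        samples.append(sample)
        ctrl.step(sample)

    return TrialRecord(
        samples=samples,
        events=list(ctrl.events),
        participant=participant,
        feet_trace=feet_trace,
    )


_PHASES = ["baseline", "train1", "train2", "train3", "train4", "train5", "retention"]


def simulate_experiment(
    schedule: LearningSchedule,
    n_agents: int,
    duration: float = 120.0,
    body_height: float = 1.75,
    constants: ControllerConstants | None = None,
    base_seed: int = 0,
    rate: float = DEFAULT_RATE_HZ,
) -> pd.DataFrame:
    """Cohort simulation over a baseline / 5-trial-training / retention
    design; returns one metrics row per agent and phase."""
    if n_agents < 1:
        raise ValueError("n_agents must be at least 1")
    constants = constants or ControllerConstants()
    participant = ParticipantModel.from_body_height(body_height, constants)
    ss = np.random.SeedSequence(base_seed)
    seeds = ss.generate_state(n_agents * len(_PHASES)).reshape(n_agents, len(_PHASES))
    rows = []
    for agent in range(n_agents):
        for k, phase in enumerate(_PHASES):
            skill = replace(schedule.skill_at(k), seed=int(seeds[agent, k] % 2**31))
            rec = simulate_trial(skill, duration, participant, constants, rate=rate)
            m = compute_metrics(rec)
            rows.append(
                {
                    "agent": agent,
                    "phase": phase,
                    "trial": k,
                    "n_steps": m.n_steps,
                    "mean_trunk_inclination": m.mean_trunk_inclination,
                    "deviation_from_target": m.deviation_from_target,
                }
            )
    return pd.DataFrame(rows)
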