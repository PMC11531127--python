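"""Frame-by-frame step-trigger state machine.

A virtual step requires three movements in strict order, mirroring how
steps are triggered in a wearable exoskeleton:

1. *Walker advance* — push the walker forward to create room ahead of
   the trailing foot.
2. *Weight shift* — move the pelvis laterally onto the leading leg
   (within a tolerance) and hold it there.
3. *Hip thrust* — accelerate the pelvis forward; the peak acceleration
   commands the stride length.

The controller consumes one :class:`KinematicSample` per frame
(nominally 90 Hz) and emits a :class:`StepEvent` when a thrust
completes with the weight shift held throughout and enough forward hip
displacement.  A commanded step longer than the room left to the
walker is a collision: the event is recorded but the avatar's foot
does not move.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

from .scaling import (
    ControllerConstants,
    ParticipantModel,
    commanded_stride_length,
    target_stride_length,
)

__all__ = [
    "Phase",
    "KinematicSample",
    "AvatarFeet",
    "ControllerState",
    "StepEvent",
    "StepController",
    "weight_shift_satisfied",
    "update",
    "peak_commit",
    "collision_check",
    "apply_step",
    "trunk_angle_of_sample",
]


class Phase(Enum):
    IDLE = "IDLE"
    WALKER_READY = "WALKER_READY"
    SHIFTED = "SHIFTED"
    THRUSTING = "THRUSTING"


@dataclass(frozen=True)
class KinematicSample:
    """One tracked frame: pelvis/head positions, walker position and
    anteroposterior pelvis acceleration (IMU channel)."""

    t: float
    pelvis_x: float
    pelvis_y: float
    pelvis_z: float
    head_x: float
    head_y: float
    head_z: float
    walker_x: float
    accel_x: float


@dataclass(frozen=True)
class AvatarFeet:
    """Anteroposterior/lateral foot coordinates of the avatar.

    ``leading`` is the foot in front of the coronal plane; on an exact
    tie the previous label is retained to avoid chatter.
    """

    left_x: float
    right_x: float
    left_y: float
    right_y: float
    leading: str  # "left" | "right"

    def __post_init__(self) -> None:
        if self.leading not in ("left", "right"):
            raise ValueError("leading must be 'left' or 'right'")

    @property
    def trailing(self) -> str:
        return "right" if self.leading == "left" else "left"

    @property
    def leading_x(self) -> float:
        return self.left_x if self.leading == "left" else self.right_x

    @property
    def leading_y(self) -> float:
        return self.left_y if self.leading == "left" else self.right_y

    @property
    def trailing_x(self) -> float:
        return self.right_x if self.leading == "left" else self.left_x

    def relabel(self) -> "AvatarFeet":
        """Recompute the leading label; ties keep the current one."""
        if self.left_x > self.right_x:
            lead = "left"
        elif self.right_x > self.left_x:
            lead = "right"
        else:
            lead = self.leading
        return replace(self, leading=lead)


@dataclass(frozen=True)
class ControllerState:
    phase: Phase = Phase.IDLE
    thrust_origin_x: float = 0.0
    running_peak: float = 0.0
    shift_held_since: float = math.nan
    last_t: float = math.nan
    # acceleration of the previous frame; +inf initially so a trace that
    # starts mid-thrust cannot trigger on its very first frame
    prev_accel: float = math.inf


@dataclass(frozen=True)
class StepEvent:
    """A committed virtual step (possibly a walker collision)."""

    t_trigger: float
    a_peak: float
    stride_length: float
    target_at_trigger: float
    trunk_inclination_at_trigger: float
    collided: bool
    stepping_foot: str


def weight_shift_satisfied(
    pelvis_y: float, leading_foot_y: float, constants: ControllerConstants
) -> bool:
    """Movement 2: pelvis laterally matched to the leading foot.

    Inclusive at the tolerance boundary.
    """
    return abs(pelvis_y - leading_foot_y) <= constants.weight_shift_tol


def collision_check(stride_length: float, trailing_foot_x: float, walker_x: float) -> bool:
    """True iff the commanded stride overshoots the walker.

    Strict inequality: a step landing exactly at the walker is legal.
    """
    if walker_x < trailing_foot_x:
        raise ValueError("walker must be ahead of the trailing foot")
    return stride_length > walker_x - trailing_foot_x


def apply_step(feet: AvatarFeet, event: StepEvent) -> AvatarFeet:
    """Advance the trailing foot by the event's stride length.

    Stride length is a same-foot contact-to-contact distance, so the
    stepping (trailing) foot translates forward by exactly that
    amount; leading/trailing labels are then recomputed.
    """
    if event.collided:
        raise ValueError("a collided step moves no foot")
    if event.stepping_foot == "left":
        feet = replace(feet, left_x=feet.left_x + event.stride_length)
    else:
        feet = replace(feet, right_x=feet.right_x + event.stride_length)
    return feet.relabel()


def peak_commit(window, constants: ControllerConstants | None = None) -> Optional[float]:
    """Offline peak extraction for a single thrust window.

    Returns the window maximum once the thrust is complete: either the
    acceleration has fallen back below ``a_min`` after exceeding it,
    or the running maximum reached ``a_max`` (early saturation
    commit).  ``None`` if ``a_min`` is never exceeded.
    """
    constants = constants or ControllerConstants()
    running = 0.0
    armed = False
    for a in window:
        running = max(running, a)
        if running >= constants.a_max:
            return running
        if a >= constants.a_min:
            armed = True
        elif armed:
            return running
    return running if armed else None


def trunk_angle_of_sample(sample: KinematicSample) -> float:
    """Trunk inclination (degrees) of one frame: angle between the
    pelvis-to-head segment and the +z vertical."""
    dx = sample.head_x - sample.pelvis_x
    dy = sample.head_y - sample.pelvis_y
    dz = sample.head_z - sample.pelvis_z
    norm = math.sqrt(dx * dx + dy * dy + dz * dz)
    if norm == 0.0:
        raise ValueError("head and pelvis coincide")
    c = max(-1.0, min(1.0, dz / norm))
    return math.degrees(math.acos(c))


def update(
    state: ControllerState,
    sample: KinematicSample,
    feet: AvatarFeet,
    participant: ParticipantModel,
    constants: ControllerConstants | None = None,
) -> tuple[ControllerState, Optional[StepEvent]]:
    """Advance the state machine by one frame.

    Transitions::

        IDLE         -> WALKER_READY  when walker_x - trailing_x >= sl_min
        WALKER_READY -> SHIFTED       when the weight shift is satisfied
        SHIFTED      -> THRUSTING     when accel_x first exceeds a_min
                                      (rising edge, shift still held)
        THRUSTING    -> commit        when accel falls below a_min or the
                                      running peak saturates at a_max

    A commit emits a StepEvent iff the pelvis advanced at least
    ``hip_disp_min`` since the thrust began and the shift was held for
    every frame of the thrust; losing the shift mid-thrust aborts the
    cycle back to WALKER_READY, and a fresh rising edge of the
    acceleration is needed to thrust again.  After any emitted event
    (collided or not) the controller returns to IDLE.
    """
    constants = constants or ControllerConstants()
    if not math.isnan(state.last_t) and sample.t <= state.last_t:
        raise ValueError(f"out-of-order timestamp {sample.t!r}")
    prev_accel = state.prev_accel
    state = replace(state, last_t=sample.t, prev_accel=sample.accel_x)

    shift_ok = weight_shift_satisfied(sample.pelvis_y, feet.leading_y, constants)
    room = sample.walker_x - feet.trailing_x

    if state.phase is Phase.IDLE:
        if room >= participant.sl_min:
            state = replace(state, phase=Phase.WALKER_READY)
        else:
            return state, None
        # fall through: the walker may already be in place and the
        # shift satisfied on this very frame

    if state.phase is Phase.WALKER_READY:
        if shift_ok:
            state = replace(state, phase=Phase.SHIFTED, shift_held_since=sample.t)
        else:
            return state, None

    if state.phase is Phase.SHIFTED:
        if not shift_ok:
            return replace(state, phase=Phase.WALKER_READY, shift_held_since=math.nan), None
        if sample.accel_x >= constants.a_min > prev_accel:
            state = replace(
                state,
                phase=Phase.THRUSTING,
                thrust_origin_x=sample.pelvis_x,
                running_peak=sample.accel_x,
            )
            return _thrusting_step(state, sample, feet, participant, constants, entered=True)
        return state, None

    # THRUSTING
    if not shift_ok:
        return (
            replace(
                state,
                phase=Phase.WALKER_READY,
                running_peak=0.0,
                shift_held_since=math.nan,
            ),
            None,
        )
    state = replace(state, running_peak=max(state.running_peak, sample.accel_x))
    return _thrusting_step(state, sample, feet, participant, constants, entered=False)


def _thrusting_step(
    state: ControllerState,
    sample: KinematicSample,
    feet: AvatarFeet,
    participant: ParticipantModel,
    constants: ControllerConstants,
    entered: bool,
) -> tuple[ControllerState, Optional[StepEvent]]:
    saturated = state.running_peak >= constants.a_max
    fell_below = (not entered) and sample.accel_x < constants.a_min
    if not (saturated or fell_below):
        return state, None

    a_peak = state.running_peak
    disp = sample.pelvis_x - state.thrust_origin_x
    if disp < constants.hip_disp_min:
        # thrust complete but no deliberate forward displacement:
        # no event; shift is still held, so retry from SHIFTED
        return (
            replace(state, phase=Phase.SHIFTED, running_peak=0.0),
            None,
        )

    stride = commanded_stride_length(a_peak, disp, participant, constants)
    collided = collision_check(stride, feet.trailing_x, sample.walker_x)
    event = StepEvent(
        t_trigger=sample.t,
        a_peak=a_peak,
        stride_length=stride,
        target_at_trigger=target_stride_length(
            participant.sl_opt, feet.leading_x, feet.trailing_x
        ),
        trunk_inclination_at_trigger=trunk_angle_of_sample(sample),
        collided=collided,
        stepping_foot=feet.trailing,
    )
    new_state = replace(
        state, phase=Phase.IDLE, running_peak=0.0, shift_held_since=math.nan
    )
    return new_state, event


@dataclass
class StepController:
    """Stateful convenience wrapper around :func:`update` that also
    moves the avatar's feet when a non-collided step is emitted."""

    participant: ParticipantModel
    feet: AvatarFeet
    constants: ControllerConstants = field(default_factory=ControllerConstants)
    state: ControllerState = field(default_factory=ControllerState)
    events: list[StepEvent] = field(default_factory=list)

    def step(self, sample: KinematicSample) -> Optional[StepEvent]:
        self.state, event = update(
            self.state, sample, self.feet, self.participant, self.constants
        )
        if event is not None:
            self.events.append(event)
            if not event.collided:
                self.feet = apply_step(self.feet, event)
        return event

    def run(self, samples) -> list[StepEvent]:
        for s in samples:
            self.step(s)
        return self.events
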