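"""Fusiform feedback-object geometry and the step score.

The concurrent visual feedback of the walking task is a spindle-shaped
object projected on the virtual floor.  Its outline is a piecewise
cubic Hermite curve over the normalized stride axis ``x = SL/SL_max``
with four keyframes and zero tangents everywhere::

    K1 = (0, 0)                   start
    K2 = (SL_min/SL_max, 0)       smallest stride that triggers a step
    K3 = (SL_target/SL_max, 1)    widest point: the target stride
    K4 = (1, 0)                   maximum stride

The same curve defines the terminal stride-length score,
``SL_score = 75 * H(SL/SL_max) + 25`` (25..100 points), which is
multiplied by a trunk-inclination factor (1..10) to give the step
score (25..1000 points).  Upright posture and on-target strides score
highest; leaning on the walker or strides near the extremes score
lowest.
"""

from __future__ import annotations

from dataclasses import dataclass

from .scaling import ControllerConstants, ParticipantModel

__all__ = [
    "FeedbackCurve",
    "FeedbackFrame",
    "StepScore",
    "build_curve",
    "eval_curve",
    "stride_score",
    "trunk_factor",
    "total_score",
    "score_step",
    "object_length",
    "walker_border_fraction",
    "fill_fraction",
    "frame_feedback",
]

# K3 is clamped below K4 when the feet are so far apart that the target
# exceeds SL_max; the Hermite construction needs strictly ordered knots.
_K3_CLAMP = 0.99

OBJECT_LENGTH_MAX = 2.0  # m, fully upright
OBJECT_LENGTH_MIN = 0.3  # m, fully inclined


@dataclass(frozen=True)
class FeedbackCurve:
    """Four (x, y) keyframes with zero tangents, x strictly increasing."""

    k1: tuple[float, float]
    k2: tuple[float, float]
    k3: tuple[float, float]
    k4: tuple[float, float]

    def __post_init__(self) -> None:
        xs = [self.k1[0], self.k2[0], self.k3[0], self.k4[0]]
        if not all(a < b for a, b in zip(xs, xs[1:])):
            raise ValueError("keyframe abscissae must be strictly increasing")

    @property
    def knots(self) -> tuple[tuple[float, float], ...]:
        return (self.k1, self.k2, self.k3, self.k4)


@dataclass(frozen=True)
class FeedbackFrame:
    """Per-frame cue state of the fusiform object (geometry only)."""

    object_length: float
    border_fraction: float
    fill_fraction: float
    lateral_offset: float
    shift_line_green: bool
    prev_stride_fraction: float


@dataclass(frozen=True)
class StepScore:
    sl_score: float
    trunk_factor: float
    total: float


def build_curve(participant: ParticipantModel, target: float) -> FeedbackCurve:
    """Construct the feedback curve for one step's target stride."""
    if target <= 0.0:
        raise ValueError("target must be positive")
    k2x = participant.sl_min / participant.sl_max
    k3x = min(target / participant.sl_max, _K3_CLAMP)
    return FeedbackCurve(k1=(0.0, 0.0), k2=(k2x, 0.0), k3=(k3x, 1.0), k4=(1.0, 0.0))


def eval_curve(curve: FeedbackCurve, x: float) -> float:
    """Evaluate the Hermite outline at normalized stride ``x`` in [0, 1].

    With all tangents zero each segment reduces to the cubic
    ``y_a * (2t^3 - 3t^2 + 1) + y_b * (-2t^3 + 3t^2)`` in the local
    segment fraction ``t`` — the classic "smoothstep" blend between
    the two knot ordinates.
    """
    if x < 0.0 or x > 1.0:
        raise ValueError("x must lie in [0, 1]")
    knots = curve.knots
    for (xa, ya), (xb, yb) in zip(knots, knots[1:]):
        if x <= xb:
            t = (x - xa) / (xb - xa)
            h00 = 2 * t**3 - 3 * t**2 + 1
            h01 = -2 * t**3 + 3 * t**2
            return ya * h00 + yb * h01
    return knots[-1][1]  # x == 1.0 handled above; defensive


def stride_score(curve: FeedbackCurve, stride_length: float, sl_max: float) -> float:
    """Stride-length score, 25..100 points."""
    if not 0.0 <= stride_length <= sl_max:
        raise ValueError("stride_length must lie in [0, sl_max]")
    return 75.0 * eval_curve(curve, stride_length / sl_max) + 25.0


def trunk_factor(
    inclination: float, constants: ControllerConstants | None = None
) -> float:
    """Trunk-inclination score factor.

    10 for inclinations at or below 15 degrees, 1 at or above 90
    degrees, linear in between.
    """
    constants = constants or ControllerConstants()
    lo, hi = constants.trunk_factor_lo_deg, constants.trunk_factor_hi_deg
    if inclination < 0.0:
        raise ValueError("inclination must be non-negative")
    if inclination <= lo:
        return 10.0
    if inclination >= hi:
        return 1.0
    return 10.0 - 9.0 * (inclination - lo) / (hi - lo)


def total_score(sl_score: float, factor: float) -> float:
    """Step score: product of stride score and trunk factor (25..1000)."""
    return sl_score * factor


def score_step(
    participant: ParticipantModel,
    stride_length: float,
    target: float,
    inclination: float,
    constants: ControllerConstants | None = None,
) -> StepScore:
    """Score one committed step (terminal feedback)."""
    curve = build_curve(participant, target)
    sl = stride_score(curve, stride_length, participant.sl_max)
    tf = trunk_factor(inclination, constants)
    return StepScore(sl_score=sl, trunk_factor=tf, total=total_score(sl, tf))


def object_length(
    inclination: float, constants: ControllerConstants | None = None
) -> float:
    """Anterior length of the fusiform object, m.

    Shrinks linearly from 2.0 m (upright, <= 15 deg) to 0.3 m
    (>= 90 deg, leaning fully on the walker).
    """
    constants = constants or ControllerConstants()
    lo, hi = constants.trunk_factor_lo_deg, constants.trunk_factor_hi_deg
    if inclination < 0.0:
        raise ValueError("inclination must be non-negative")
    if inclination <= lo:
        return OBJECT_LENGTH_MAX
    if inclination >= hi:
        return OBJECT_LENGTH_MIN
    span = OBJECT_LENGTH_MAX - OBJECT_LENGTH_MIN
    return OBJECT_LENGTH_MAX - span * (inclination - lo) / (hi - lo)


def walker_border_fraction(walker_x: float, trailing_foot_x: float, sl_max: float) -> float:
    """Position of the light/dark border along the object.

    The walker-to-trailing-leg distance normalized by ``SL_max``;
    strides beyond this fraction would collide with the walker.
    """
    if walker_x < trailing_foot_x:
        raise ValueError("walker must be ahead of the trailing foot")
    return min((walker_x - trailing_foot_x) / sl_max, 1.0)


def fill_fraction(running_peak: float, a_max: float) -> float:
    """Opaque-layer fill during the hip thrust: the running peak
    acceleration normalized by ``a_max``, saturating at 1."""
    if running_peak < 0.0:
        raise ValueError("running_peak must be non-negative")
    return min(running_peak / a_max, 1.0)


def frame_feedback(
    state,
    sample,
    feet,
    participant: ParticipantModel,
    prev_event=None,
    constants: ControllerConstants | None = None,
) -> FeedbackFrame:
    """Assemble all concurrent cues for one frame.

    ``state``/``sample``/``feet`` are the trigger controller's
    per-frame objects; ``prev_event`` the last committed step, if any
    (its stride drives the yellow previous-stride line).
    """
    from .trigger import trunk_angle_of_sample, weight_shift_satisfied

    constants = constants or ControllerConstants()
    inclination = trunk_angle_of_sample(sample)
    prev_fraction = 0.0
    if prev_event is not None and not prev_event.collided:
        prev_fraction = min(prev_event.stride_length / participant.sl_max, 1.0)
    return FeedbackFrame(
        object_length=object_length(inclination, constants),
        border_fraction=walker_border_fraction(
            sample.walker_x, feet.trailing_x, participant.sl_max
        ),
        fill_fraction=fill_fraction(state.running_peak, constants.a_max),
        lateral_offset=sample.pelvis_y,
        shift_line_green=weight_shift_satisfied(
            sample.pelvis_y, feet.leading_y, constants
        ),
        prev_stride_fraction=prev_fraction,
    )
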