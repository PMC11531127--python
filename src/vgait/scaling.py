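"""Participant scaling and the stride-length control law.

The virtual-walking task commands the length of each virtual step from
the peak anteroposterior pelvis acceleration produced during a "hip
thrust".  All stride lengths are derived from the participant's body
height: the optimal stride length ``SL_opt`` is half the average
healthy-adult stride length (expressed as a fraction of body height),
the saturation length ``SL_max`` is ``1.5 * SL_opt``, and the smallest
commandable stride ``SL_min`` is the one produced at the minimum
trigger acceleration, ``(a_min / a_max) * SL_max``.

Units: lengths in metres, accelerations in m/s^2, angles in degrees.
Axes: +x anteroposterior (forward), +y lateral (leftward), +z up.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ControllerConstants",
    "ParticipantModel",
    "optimal_stride_length",
    "max_stride_length",
    "target_stride_length",
    "commanded_stride_length",
]


@dataclass(frozen=True)
class ControllerConstants:
    """Fixed controller constants of the task engine.

    Parameters
    ----------
    a_max
        Acceleration at which the commanded stride saturates, m/s^2.
    a_min
        Minimum peak acceleration that triggers a step, m/s^2.
    hip_disp_min
        Minimum anteroposterior hip displacement during the thrust,
        m; guards against accidental triggers.
    weight_shift_tol
        Lateral pelvis-to-leading-foot tolerance for a valid weight
        shift, m.
    sl_avg_frac
        Average healthy-adult stride length as a fraction of body
        height (dimensionless).
    sl_max_factor
        Multiplier taking the optimal stride length to the maximum
        commandable one (dimensionless).
    trunk_factor_lo_deg, trunk_factor_hi_deg
        Trunk-inclination angles (degrees) bounding the linear ramps
        of the trunk score factor and of the feedback-object length.
    """

    a_max: float = 0.4
    a_min: float = 0.1
    hip_disp_min: float = 0.02
    weight_shift_tol: float = 0.15
    sl_avg_frac: float = 0.7774
    sl_max_factor: float = 1.5
    trunk_factor_lo_deg: float = 15.0
    trunk_factor_hi_deg: float = 90.0

    def __post_init__(self) -> None:
        if not 0.0 < self.a_min < self.a_max:
            raise ValueError("require 0 < a_min < a_max")
        if self.hip_disp_min <= 0.0:
            raise ValueError("hip_disp_min must be positive")
        if self.weight_shift_tol <= 0.0:
            raise ValueError("weight_shift_tol must be positive")
        if self.sl_avg_frac < 0.0:
            raise ValueError("sl_avg_frac must be non-negative")
        if not self.trunk_factor_lo_deg < self.trunk_factor_hi_deg:
            raise ValueError("trunk factor bounds must be ordered")


@dataclass(frozen=True)
class ParticipantModel:
    """Body height and the stride lengths derived from it."""

    body_height: float
    sl_opt: float
    sl_max: float
    sl_min: float

    @classmethod
    def from_body_height(
        cls, body_height: float, constants: ControllerConstants | None = None
    ) -> "ParticipantModel":
        constants = constants or ControllerConstants()
        sl_opt = optimal_stride_length(body_height, constants)
        sl_max = max_stride_length(sl_opt, constants)
        sl_min = (constants.a_min / constants.a_max) * sl_max
        return cls(body_height=body_height, sl_opt=sl_opt, sl_max=sl_max, sl_min=sl_min)

    def __post_init__(self) -> None:
        if self.body_height <= 0.0:
            raise ValueError("body_height must be positive")
        if not 0.0 < self.sl_min < self.sl_opt < self.sl_max:
            raise ValueError("require 0 < sl_min < sl_opt < sl_max")


def optimal_stride_length(
    body_height: float, constants: ControllerConstants | None = None
) -> float:
    """Optimal stride length: half the average stride for this height.

    ``SL_opt = 0.5 * sl_avg_frac * body_height``.  Half, because users
    of wearable exoskeletons tend to take shorter steps than
    unimpaired walkers.
    """
    constants = constants or ControllerConstants()
    if body_height <= 0.0:
        raise ValueError("body_height must be positive")
    return 0.5 * constants.sl_avg_frac * body_height


def max_stride_length(
    sl_opt: float, constants: ControllerConstants | None = None
) -> float:
    """Maximum commandable stride length, ``sl_max_factor * SL_opt``."""
    constants = constants or ControllerConstants()
    if sl_opt <= 0.0:
        raise ValueError("sl_opt must be positive")
    return constants.sl_max_factor * sl_opt


def target_stride_length(
    sl_opt: float, leading_foot_pos: float, trailing_foot_pos: float
) -> float:
    """Per-step target stride length.

    ``SL_target = 0.5 * SL_opt + |leading - trailing|``: the stride
    the trailing foot must take so the avatar lands in a symmetric
    stance of width ``SL_opt / 2``, i.e. so the next same-foot
    contact-to-contact distance is the optimal one.  Iterating this
    rule converges to strides of exactly ``SL_opt``.
    """
    if sl_opt <= 0.0:
        raise ValueError("sl_opt must be positive")
    return 0.5 * sl_opt + abs(leading_foot_pos - trailing_foot_pos)


def commanded_stride_length(
    a_peak: float,
    hip_x_disp: float,
    participant: ParticipantModel,
    constants: ControllerConstants | None = None,
) -> float:
    """Stride length commanded by a hip thrust.

    Piecewise-linear in the thrust's peak acceleration::

        SL = (a_peak / a_max) * SL_max   if a_min <= a_peak < a_max
                                          and hip displacement >= threshold
        SL = SL_max                      if a_peak >= a_max and displacement ok
        SL = 0                           otherwise

    The hip-displacement gate (2 cm by default) filters accidental
    accelerometer spikes that do not correspond to a deliberate
    forward thrust.
    """
    constants = constants or ControllerConstants()
    if a_peak < 0.0:
        raise ValueError("a_peak must be non-negative")
    if hip_x_disp < 0.0:
        raise ValueError("hip_x_disp must be non-negative")
    if hip_x_disp < constants.hip_disp_min:
        return 0.0
    if a_peak >= constants.a_max:
        return participant.sl_max
    if a_peak >= constants.a_min:
        return (a_peak / constants.a_max) * participant.sl_max
    return 0.0
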