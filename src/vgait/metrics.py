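"""Gait outcome metrics for one trial.

Three metrics summarize a trial of the virtual walking task:

- **number of steps** — non-collided step events (main outcome; more
  steps means more proficient triggering);
- **mean trunk inclination** — the head-to-pelvis segment's angular
  deviation from the calibrated vertical, averaged over every frame of
  the trial (degrees; large values mean leaning on the walker);
- **deviation from the target stride length** — mean absolute
  percentage difference between each step's stride and its target,
  undefined when the trial contains no steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .scaling import ParticipantModel
from .trigger import KinematicSample, StepEvent

__all__ = [
    "TrialRecord",
    "TrialMetrics",
    "trunk_angle",
    "count_steps",
    "mean_trunk_inclination",
    "stride_deviation",
    "compute_metrics",
]

_UP = (0.0, 0.0, 1.0)


@dataclass
class TrialRecord:
    """All samples and step events of one trial."""

    samples: Sequence[KinematicSample]
    events: Sequence[StepEvent]
    participant: ParticipantModel
    calibration_up: tuple[float, float, float] = _UP
    feet_trace: Optional[Sequence] = None  # per-frame AvatarFeet, when simulated

    def __post_init__(self) -> None:
        if self.samples and self.events:
            t0, t1 = self.samples[0].t, self.samples[-1].t
            for e in self.events:
                if not t0 <= e.t_trigger <= t1:
                    raise ValueError("event timestamp outside sample span")


@dataclass(frozen=True)
class TrialMetrics:
    n_steps: int
    mean_trunk_inclination: float
    deviation_from_target: Optional[float]  # percent; None when no steps


def trunk_angle(
    head_pos: Sequence[float],
    pelvis_pos: Sequence[float],
    up: Sequence[float] = _UP,
) -> float:
    """Angle (degrees) between the pelvis-to-head segment and ``up``."""
    seg = np.asarray(head_pos, dtype=float) - np.asarray(pelvis_pos, dtype=float)
    n = np.linalg.norm(seg)
    if n == 0.0:
        raise ValueError("head and pelvis coincide")
    u = np.asarray(up, dtype=float)
    c = float(np.dot(seg, u) / (n * np.linalg.norm(u)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def count_steps(record: TrialRecord) -> int:
    """Number of completed (non-collided) steps."""
    return sum(1 for e in record.events if not e.collided)


def mean_trunk_inclination(record: TrialRecord) -> float:
    """Frame-wise mean trunk inclination over the whole trial, degrees."""
    if not record.samples:
        raise ValueError("trial has no samples")
    up = record.calibration_up
    angles = [
        trunk_angle(
            (s.head_x, s.head_y, s.head_z), (s.pelvis_x, s.pelvis_y, s.pelvis_z), up
        )
        for s in record.samples
    ]
    return float(np.mean(angles))


def stride_deviation(record: TrialRecord) -> Optional[float]:
    """Mean absolute percent deviation of stride from target.

    ``None`` (undefined, not zero) when the trial has no completed
    steps — trials without a single step carry no stride information.
    """
    devs = [
        100.0 * abs(e.stride_length - e.target_at_trigger) / e.target_at_trigger
        for e in record.events
        if not e.collided
    ]
    if not devs:
        return None
    return float(np.mean(devs))


def compute_metrics(record: TrialRecord) -> TrialMetrics:
    """All three outcome metrics for one trial."""
    return TrialMetrics(
        n_steps=count_steps(record),
        mean_trunk_inclination=mean_trunk_inclination(record),
        deviation_from_target=stride_deviation(record),
    )
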