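"""Trace/config file formats and the batch pipeline.

Kinematic traces are plain CSV (UTF-8, '.' decimal separator) with one
row per 90 Hz frame and the exact header::

    t,pelvis_x,pelvis_y,pelvis_z,head_x,head_y,head_z,walker_x,accel_x,
    foot_left_x,foot_left_y,foot_right_x,foot_right_y

Foot positions are carried in the trace (the avatar/IK layer that
would produce them from hardware is out of scope).  Step events are
written as JSONL (one object per event, including its score); metrics
as a one-row CSV per trial.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .feedback import score_step
from .metrics import TrialMetrics, TrialRecord, compute_metrics
from .scaling import ControllerConstants, ParticipantModel
from .trigger import AvatarFeet, ControllerState, KinematicSample, Phase, update

logger = logging.getLogger("vgait")

TRACE_COLUMNS = [
    "t",
    "pelvis_x",
    "pelvis_y",
    "pelvis_z",
    "head_x",
    "head_y",
    "head_z",
    "walker_x",
    "accel_x",
    "foot_left_x",
    "foot_left_y",
    "foot_right_x",
    "foot_right_y",
]

NOMINAL_DT = 1.0 / 90.0

__all__ = [
    "TRACE_COLUMNS",
    "RunConfig",
    "load_config",
    "read_trace",
    "write_trace",
    "write_events",
    "read_events",
    "write_metrics",
    "replay_trace",
    "run_pipeline",
]


@dataclass(frozen=True)
class RunConfig:
    """Participant, controller constants and simulation settings."""

    body_height: float = 1.75
    constants: ControllerConstants = field(default_factory=ControllerConstants)
    duration: float = 120.0
    rate: float = 90.0
    seed: int = 0
    skill: dict = field(default_factory=dict)  # AgentSkill overrides for `simulate`

    @property
    def participant(self) -> ParticipantModel:
        return ParticipantModel.from_body_height(self.body_height, self.constants)


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML/JSON run configuration.

    Absent keys fall back to the engine defaults; unknown keys are
    rejected so typos cannot silently disable a constant.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {"participant", "constants", "simulation", "skill"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")

    part = raw.get("participant") or {}
    _reject_unknown(part, {"body_height"}, path, "participant")
    const_raw = raw.get("constants") or {}
    const_fields = set(ControllerConstants.__dataclass_fields__)
    _reject_unknown(const_raw, const_fields, path, "constants")
    sim = raw.get("simulation") or {}
    _reject_unknown(sim, {"duration", "rate", "seed"}, path, "simulation")
    skill = raw.get("skill") or {}

    return RunConfig(
        body_height=float(part.get("body_height", 1.75)),
        constants=ControllerConstants(**const_raw),
        duration=float(sim.get("duration", 120.0)),
        rate=float(sim.get("rate", 90.0)),
        seed=int(sim.get("seed", 0)),
        skill=dict(skill),
    )


def _reject_unknown(block: dict, allowed: set, path, name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown keys in '{name}' block: {sorted(unknown)}")


def read_trace(path: str | Path) -> tuple[list[KinematicSample], list[AvatarFeet]]:
    """Read a trace CSV into typed samples and the per-frame feet.

    The header must match :data:`TRACE_COLUMNS` exactly and timestamps
    must strictly increase; sampling-interval jitter beyond 20% of the
    nominal 1/90 s is logged as a warning, never an error.
    """
    df = pd.read_csv(path)
    if list(df.columns) != TRACE_COLUMNS:
        raise ValueError(f"{path}: bad header; expected {TRACE_COLUMNS}")
    if df.isna().any().any():
        row = int(df[df.isna().any(axis=1)].index[0]) + 2
        raise ValueError(f"{path}: missing cell at line {row}")
    t = df["t"].to_numpy()
    bad = (t[1:] <= t[:-1]).nonzero()[0]
    if bad.size:
        raise ValueError(f"{path}: non-increasing t at line {int(bad[0]) + 3}")
    dts = t[1:] - t[:-1]
    if dts.size and (abs(dts - NOMINAL_DT) > 0.2 * NOMINAL_DT).any():
        logger.warning("%s: sampling interval deviates >20%% from 1/90 s", path)

    samples = [
        KinematicSample(
            t=r.t,
            pelvis_x=r.pelvis_x,
            pelvis_y=r.pelvis_y,
            pelvis_z=r.pelvis_z,
            head_x=r.head_x,
            head_y=r.head_y,
            head_z=r.head_z,
            walker_x=r.walker_x,
            accel_x=r.accel_x,
        )
        for r in df.itertuples(index=False)
    ]
    feet: list[AvatarFeet] = []
    lead = "left"
    for r in df.itertuples(index=False):
        if r.foot_left_x > r.foot_right_x:
            lead = "left"
        elif r.foot_right_x > r.foot_left_x:
            lead = "right"
        feet.append(
            AvatarFeet(
                left_x=r.foot_left_x,
                right_x=r.foot_right_x,
                left_y=r.foot_left_y,
                right_y=r.foot_right_y,
                leading=lead,
            )
        )
    return samples, feet


def write_trace(path: str | Path, record: TrialRecord) -> None:
    """Write a simulated trial's trace (including per-frame feet) as CSV."""
    if record.feet_trace is None or len(record.feet_trace) != len(record.samples):
        raise ValueError("record carries no per-frame feet to write")
    rows = []
    for s, f in zip(record.samples, record.feet_trace):
        rows.append(
            [
                s.t,
                s.pelvis_x,
                s.pelvis_y,
                s.pelvis_z,
                s.head_x,
                s.head_y,
                s.head_z,
                s.walker_x,
                s.accel_x,
                f.left_x,
                f.left_y,
                f.right_x,
                f.right_y,
            ]
        )
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(
        path, index=False, float_format="%.9f"
    )


def write_events(path: str | Path, record: TrialRecord) -> None:
    """Append-friendly JSONL: one object per step event, with its score."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in record.events:
            obj = asdict(e)
            score = score_step(
                record.participant,
                min(e.stride_length, record.participant.sl_max),
                e.target_at_trigger,
                e.trunk_inclination_at_trigger,
            )
            obj.update(
                sl_score=score.sl_score,
                trunk_factor=score.trunk_factor,
                score=score.total,
            )
            fh.write(json.dumps(obj) + "\n")


def read_events(path: str | Path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        return [json.loads(line) for line in fh if line.strip()]


def write_metrics(path: str | Path, metrics: TrialMetrics) -> None:
    """One-row metrics CSV; an undefined deviation is an empty cell."""
    pd.DataFrame(
        [
            {
                "n_steps": metrics.n_steps,
                "mean_trunk_inclination": metrics.mean_trunk_inclination,
                "deviation_from_target": metrics.deviation_from_target,
            }
        ]
    ).to_csv(path, index=False)


def replay_trace(
    samples: list[KinematicSample],
    feet: list[AvatarFeet],
    participant: ParticipantModel,
    constants: ControllerConstants | None = None,
) -> TrialRecord:
    """Run the trigger controller over a recorded trace.

    The feet columns of the trace are trusted as the avatar's ground
    truth (they already reflect any steps taken during recording), so
    the controller only reads them and never moves them.
    """
    constants = constants or ControllerConstants()
    state = ControllerState()
    events = []
    for s, f in zip(samples, feet):
        prev_phase = state.phase
        state, event = update(state, s, f, participant, constants)
        if event is not None:
            events.append(event)
            if event.collided:
                logger.info("t=%.3f collided step rejected", event.t_trigger)
            else:
                logger.info(
                    "t=%.3f step a_peak=%.3f SL=%.3f", event.t_trigger, event.a_peak,
                    event.stride_length,
                )
        elif prev_phase is Phase.THRUSTING and state.phase is Phase.WALKER_READY:
            logger.info("t=%.3f thrust aborted: weight shift lost", s.t)
    return TrialRecord(
        samples=samples, events=events, participant=participant, feet_trace=feet
    )


def run_pipeline(
    config: RunConfig,
    trace_path: Optional[str | Path] = None,
    simulate: bool = False,
    out_dir: str | Path = ".",
) -> TrialMetrics:
    """Full trial pipeline: (simulate or read) -> trigger -> score -> metrics.

    Writes ``trace.csv`` (simulation only), ``results.jsonl`` and
    ``metrics.csv`` to ``out_dir``; deterministic for fixed config and
    seed.
    """
    if simulate == (trace_path is not None):
        raise ValueError("provide exactly one of trace_path or simulate=True")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participant = config.participant
    if simulate:
        from .synthetic import AgentSkill, simulate_trial

        skill = AgentSkill(**{**config.skill, "seed": config.seed})
        record = simulate_trial(
            skill, config.duration, participant, config.constants, rate=config.rate
        )
        write_trace(out / "trace.csv", record)
    else:
        samples, feet = read_trace(trace_path)
        record = replay_trace(samples, feet, participant, config.constants)
    write_events(out / "results.jsonl", record)
    if record.samples:
        metrics = compute_metrics(record)
    else:
        metrics = TrialMetrics(0, float("nan"), None)
    write_metrics(out / "metrics.csv", metrics)
    return metrics
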