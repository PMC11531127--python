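from dataclasses import replace

import numpy as np
import pytest

from offline_oracle import offline_events
from vgait import (
    AgentSkill,
    AvatarFeet,
    ControllerConstants,
    KinematicSample,
    ParticipantModel,
    StepController,
    apply_step,
    collision_check,
    commanded_stride_length,
    peak_commit,
    simulate_trial,
    weight_shift_satisfied,
)
from vgait.trigger import StepEvent


def make_sample(t, pelvis_x=0.0, pelvis_y=0.2, walker_x=2.0, accel_x=0.0):
    return KinematicSample(
        t=t,
        pelvis_x=pelvis_x,
        pelvis_y=pelvis_y,
        pelvis_z=1.0,
        head_x=pelvis_x,
        head_y=pelvis_y,
        head_z=1.7,
        walker_x=walker_x,
        accel_x=accel_x,
    )


FEET = AvatarFeet(left_x=0.0, right_x=0.0, left_y=0.2, right_y=-0.2, leading="left")


class TestWeightShift:
    @pytest.mark.parametrize(
        "pelvis_y,foot_y,expected",
        [
            (0.10, 0.12, True),
            (0.40, 0.12, False),
            (0.15, 0.0, True),  # boundary |d| = tol is inclusive
        ],
    )
    def test_tolerance(self, constants, pelvis_y, foot_y, expected):
        assert weight_shift_satisfied(pelvis_y, foot_y, constants) is expected


class TestPeakCommit:
    def test_commit_on_fallback(self):
        assert peak_commit([0, 0.05, 0.15, 0.30, 0.25, 0.08]) == pytest.approx(0.30)

    def test_never_exceeds_threshold(self):
        assert peak_commit([0, 0.05, 0.02]) is None

    def test_early_saturation_commit(self):
        assert peak_commit([0, 0.2, 0.45]) == pytest.approx(0.45)


class TestCollision:
    @pytest.mark.parametrize(
        "sl,trailing,walker,expected",
        [(0.9, 0.0, 0.8, True), (0.7, 0.0, 0.8, False), (0.8, 0.0, 0.8, False)],
    )
    def test_collision_boundary(self, sl, trailing, walker, expected):
        assert collision_check(sl, trailing, walker) is expected

    def test_walker_behind_foot_rejected(self):
        with pytest.raises(ValueError):
            collision_check(0.5, 1.0, 0.5)


class TestApplyStep:
    @staticmethod
    def event(sl, foot):
        return StepEvent(
            t_trigger=0.0,
            a_peak=0.3,
            stride_length=sl,
            target_at_trigger=sl,
            trunk_inclination_at_trigger=0.0,
            collided=False,
            stepping_foot=foot,
        )

    def test_trailing_foot_advances_by_stride(self):
        feet = AvatarFeet(left_x=0.35, right_x=0.0, left_y=0.2, right_y=-0.2, leading="left")
        out = apply_step(feet, self.event(0.6997, "right"))
        assert out.right_x == pytest.approx(0.6997)
        assert out.left_x == pytest.approx(0.35)
        assert out.leading == "right"

    def test_collided_event_rejected(self):
        ev = replace(self.event(0.5, "right"), collided=True)
        with pytest.raises(ValueError):
            apply_step(FEET, ev)

    def test_two_target_steps_keep_half_optimal_stance(self, participant):
        """Recursion of the target rule: consecutive on-target steps from
        co-located feet keep the inter-foot distance at sl_opt/2."""
        feet = FEET
        for _ in range(2):
            d = abs(feet.left_x - feet.right_x)
            target = 0.5 * participant.sl_opt + d
            feet = apply_step(feet, self.event(target, feet.trailing))
            assert abs(feet.left_x - feet.right_x) == pytest.approx(
                0.34983, abs=1e-9
            )

    def test_leading_tie_keeps_previous_label(self):
        feet = AvatarFeet(left_x=0.3, right_x=0.3, left_y=0.2, right_y=-0.2, leading="right")
        assert feet.relabel().leading == "right"


def run_cycle(peak, release_midthrust=False, hold_shift=True, participant=None):
    """Hand-built cycle: walker ahead, shift held, raised-cosine-ish thrust."""
    participant = participant or ParticipantModel.from_body_height(1.80)
    ctrl = StepController(participant=participant, feet=FEET)
    t, dt = 0.0, 1 / 90
    samples = []
    # shift onto the leading (left, y=0.2) foot, walker 2 m ahead
    for i in range(30):
        samples.append(make_sample(t, pelvis_y=0.2))
        t += dt
    # thrust: triangular accel profile peaking exactly at `peak`
    n = 91
    x = 0.0
    for i in range(n):
        frac = i / (n - 1)
        a = peak * (1 - abs(2 * frac - 1))
        x += 0.001  # 1 mm per frame -> 9 cm over the thrust
        y = 0.2
        if release_midthrust and 40 <= i < n:
            y = 0.6  # shift dropped
        if not hold_shift:
            y = 0.6
        samples.append(make_sample(t, pelvis_x=x, pelvis_y=y, accel_x=a))
        t += dt
    # tail
    for i in range(30):
        samples.append(make_sample(t, pelvis_x=x, pelvis_y=0.2))
        t += dt
    ctrl.run(samples)
    return ctrl


class TestUpdateCycles:
    def test_perfect_cycle_emits_one_step(self):
        ctrl = run_cycle(peak=0.3)
        assert len(ctrl.events) == 1
        ev = ctrl.events[0]
        assert ev.a_peak == pytest.approx(0.3)
        assert not ev.collided
        assert ev.stride_length == pytest.approx(
            commanded_stride_length(0.3, 0.05, ctrl.participant), rel=1e-12
        )

    def test_shift_released_midthrust_aborts(self):
        ctrl = run_cycle(peak=0.3, release_midthrust=True)
        assert ctrl.events == []

    def test_peak_below_minimum_never_triggers(self):
        ctrl = run_cycle(peak=0.08)
        assert ctrl.events == []

    def test_no_shift_no_step(self):
        ctrl = run_cycle(peak=0.3, hold_shift=False)
        assert ctrl.events == []

    def test_out_of_order_timestamps_rejected(self, participant):
        ctrl = StepController(participant=participant, feet=FEET)
        ctrl.step(make_sample(0.0))
        with pytest.raises(ValueError):
            ctrl.step(make_sample(0.0))

    def test_collision_blocks_foot_motion(self, participant):
        # walker barely ahead: commanded stride overshoots the room
        ctrl = StepController(participant=participant, feet=FEET)
        t, dt = 0.0, 1 / 90
        samples = []
        for _ in range(10):
            samples.append(make_sample(t, pelvis_y=0.2, walker_x=0.3))
            t += dt
        x = 0.0
        for i in range(90):
            frac = i / 89
            a = 0.3 * (1 - abs(2 * frac - 1))
            x += 0.001
            samples.append(
                make_sample(t, pelvis_x=x, pelvis_y=0.2, walker_x=0.3, accel_x=a)
            )
            t += dt
        samples.append(make_sample(t, pelvis_x=x, pelvis_y=0.2, walker_x=0.3))
        ctrl.run(samples)
        assert len(ctrl.events) == 1
        assert ctrl.events[0].collided
        assert ctrl.feet.left_x == 0.0 and ctrl.feet.right_x == 0.0


class TestStreamProperties:
    # the triangular thrust's supra-threshold run spans frames 16..74 of
    # the thrust phase, with the commit falling on frame 75
    @pytest.mark.parametrize("release_frame", [16, 40, 74, 75])
    def test_continuity_of_hold(self, release_frame):
        """One frame of lost weight shift inside the thrust window (from
        the rising edge of the acceleration to the commit) removes the
        step entirely."""
        participant = ParticipantModel.from_body_height(1.80)
        ctrl = StepController(participant=participant, feet=FEET)
        t, dt = 0.0, 1 / 90
        samples = []
        for _ in range(30):
            samples.append(make_sample(t, pelvis_y=0.2))
            t += dt
        x = 0.0
        for i in range(91):
            frac = i / 90
            a = 0.3 * (1 - abs(2 * frac - 1))
            x += 0.001
            y = 0.6 if i == release_frame else 0.2
            samples.append(make_sample(t, pelvis_x=x, pelvis_y=y, accel_x=a))
            t += dt
        samples.append(make_sample(t, pelvis_x=x, pelvis_y=0.2))
        ctrl.run(samples)
        assert ctrl.events == []

    def test_sequential_order_of_movements(self, participant):
        """No step without walker-room, shift and thrust phases entered in
        that order since the previous step."""
        from vgait.trigger import ControllerState, Phase, update

        rec = simulate_trial(AgentSkill(seed=11), 60.0, participant)
        state = ControllerState()
        since_last = []
        n_events = 0
        for s, f in zip(rec.samples, rec.feet_trace):
            state, event = update(state, s, f, participant)
            since_last.append(state.phase)
            if event is not None:
                n_events += 1
                order = [
                    next(
                        (i for i, p in enumerate(since_last) if p is ph),
                        None,
                    )
                    for ph in (Phase.WALKER_READY, Phase.SHIFTED, Phase.THRUSTING)
                ]
                assert None not in order and order == sorted(order)
                since_last = []
        assert n_events > 0

    def test_events_match_offline_oracle_and_commanded_stride(self):
        """FSM events equal the brute-force offline scan, and every stride
        equals the pure control law applied to (a_peak, displacement)."""
        rng = np.random.default_rng(7)
        participant = ParticipantModel.from_body_height(1.75)
        constants = ControllerConstants()
        for rep in range(25):
            skill = AgentSkill(
                thrust_mean=None if rep % 2 else float(rng.uniform(0.05, 0.5)),
                thrust_sd=float(rng.uniform(0, 0.12)),
                shift_noise_sd=float(rng.uniform(0, 0.05)),
                shift_hold_reliability=float(rng.uniform(0.3, 1.0)),
                cycle_period=float(rng.uniform(3.0, 6.0)),
                seed=int(rng.integers(0, 2**31)),
            )
            rec = simulate_trial(skill, 20.0, participant, constants)
            oracle = offline_events(
                rec.samples, rec.feet_trace[0], participant, constants
            )
            assert len(oracle) == len(rec.events)
            for a, b in zip(rec.events, oracle):
                assert a.t_trigger == b.t_trigger
                assert a.a_peak == pytest.approx(b.a_peak, abs=1e-12)
                assert a.stride_length == pytest.approx(b.stride_length, abs=1e-12)
                assert a.collided == b.collided
                assert a.stepping_foot == b.stepping_foot
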