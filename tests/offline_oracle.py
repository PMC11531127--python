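"""Brute-force offline re-derivation of step events from a trace.

Independent cross-check for the streaming trigger controller: instead
of a per-frame state machine, this scans the whole acceleration
channel at once, enumerates the maximal supra-threshold runs
(``accel >= a_min``, each beginning at a rising edge), and applies the
three trigger conditions (walker room latched beforehand, continuous
weight-shift hold from the run's start to the commit frame, hip
displacement over the thrust) independently to each run.
"""

import numpy as np

from vgait.scaling import commanded_stride_length, target_stride_length
from vgait.trigger import StepEvent, apply_step, trunk_angle_of_sample


def offline_events(samples, feet0, participant, constants):
    n = len(samples)
    acc = np.array([s.accel_x for s in samples])
    py = np.array([s.pelvis_y for s in samples])
    px = np.array([s.pelvis_x for s in samples])
    wx = np.array([s.walker_x for s in samples])

    feet = feet0
    events = []
    reset = 0  # first frame eligible for the walker-room latch

    def room_latched(upto):
        if upto < reset:
            return False
        return bool(
            (wx[reset : upto + 1] - feet.trailing_x >= participant.sl_min).any()
        )

    def shift_ok(i):
        return abs(py[i] - feet.leading_y) <= constants.weight_shift_tol

    def commit(start, frame, peak):
        nonlocal feet, reset
        disp = px[frame] - px[start]
        if disp < constants.hip_disp_min:
            return  # thrust complete but not deliberate: no event
        stride = commanded_stride_length(peak, disp, participant, constants)
        collided = stride > wx[frame] - feet.trailing_x
        ev = StepEvent(
            t_trigger=samples[frame].t,
            a_peak=peak,
            stride_length=stride,
            target_at_trigger=target_stride_length(
                participant.sl_opt, feet.leading_x, feet.trailing_x
            ),
            trunk_inclination_at_trigger=trunk_angle_of_sample(samples[frame]),
            collided=collided,
            stepping_foot=feet.trailing,
        )
        events.append(ev)
        if not collided:
            feet = apply_step(feet, ev)
        reset = frame + 1

    # maximal runs with acc >= a_min (inclusive bounds)
    supra = acc >= constants.a_min
    idx = np.flatnonzero(np.diff(np.concatenate(([False], supra, [False]))))
    for s0, e0 in zip(idx[0::2], idx[1::2] - 1):
        if s0 == 0:
            continue  # no rising edge at the first frame of a trace
        if not (shift_ok(s0) and room_latched(s0)):
            continue  # the rising edge passes unarmed; nothing this run
        peak, j, outcome = 0.0, s0, None
        while j <= e0:
            if not shift_ok(j):
                outcome = "abort"
                break
            peak = max(peak, acc[j])
            if peak >= constants.a_max:
                outcome = "saturate"
                break
            j += 1
        if outcome == "abort":
            continue
        if outcome == "saturate":
            commit(s0, j, peak)
            continue
        # acceleration fell below a_min at e0 + 1: commit there if the
        # trace continues and the shift is still held
        if e0 + 1 < n and shift_ok(e0 + 1):
            commit(s0, e0 + 1, peak)
    return events
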