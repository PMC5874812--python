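"""Discrete-event replay of a full treatment delivery.

The simulator schedules every machine action — initialization, per-head
step-and-shoot segment delivery with per-leaf command/arrival events, and
inter-group gantry rotations — on an exact event timeline.  Heads of one
group run independently and in parallel; the gantry advances when the
group's last head turns its beam off.  Because the schedule is built from
the same timing primitives as the closed-form predictor, the final event
time must agree with the predicted total to floating-point accuracy; the
simulator therefore serves as the brute-force verification oracle for the
predictor (and as a data source for Gantt-style delivery animations).

Leaf motion into each group's first segment happens while the gantry is
still rotating and is assumed to finish in time; if a transition would
outlast the rotation the simulator emits a warning rather than stretching
the rotation (the behavior of the real machine in that corner is
unobserved).
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .gantry_model import predict_rotation_time, reorder_groups
from .mlc_model import plan_leaf_commands, transition_time
from .plan_model import (
    MLCAperture,
    SourceCalibration,
    TimingParams,
    TreatmentPlan,
)
from .source_decay import beam_on_time, dose_rate_on

__all__ = ["DeliveryEvent", "simulate", "export_timeline", "read_timeline"]

EVENT_KINDS = (
    "init_end",
    "rotation_start",
    "rotation_end",
    "leaf_command",
    "leaf_arrival",
    "beam_on",
    "beam_off",
)

# causal precedence at equal timestamps: initialization completes before the
# first beam fires; a group's last beam-off precedes the rotation it
# triggers; a rotation ends before the next group's beams turn on
_TIE_ORDER = {
    "init_end": 0,
    "beam_off": 1,
    "rotation_start": 2,
    "rotation_end": 3,
    "leaf_command": 4,
    "leaf_arrival": 5,
    "beam_on": 6,
}


@dataclass(frozen=True)
class DeliveryEvent:
    """One timestamped machine action.

    ``head`` is ``"1"``/``"2"``/``"3"`` for head-local events and
    ``"gantry"`` for initialization and rotations; ``detail`` is a short
    free-text tag (segment index, leaf id, or swept angles).
    """

    time_s: float
    head: str
    kind: str
    detail: str = ""


def simulate(
    plan: TreatmentPlan,
    calibration: SourceCalibration,
    treatment_date: dt.date,
    params: TimingParams | None = None,
) -> tuple[list[DeliveryEvent], float]:
    """Replay ``plan`` and return (time-ordered events, end time in s).

    Deterministic: there is no randomness anywhere in the machine model.
    """
    if params is None:
        params = TimingParams()
    ordered, diffs = reorder_groups(plan)
    events: list[DeliveryEvent] = []

    t = params.t_initial
    events.append(
        DeliveryEvent(t, "gantry", "init_end", f"at {ordered[0].gantry_angle:g} deg")
    )
    group_start = t
    last_aperture: dict[int, MLCAperture] = {}
    group_end = group_start
    for gi, group in enumerate(ordered):
        head_ends = []
        for beam in group.beams:
            head = str(beam.head)
            dr = dose_rate_on(calibration, beam.head, treatment_date)
            t = group_start
            for si, seg in enumerate(beam.segments):
                if si > 0:
                    prev = beam.segments[si - 1].aperture
                    t_off = t
                    for mv in plan_leaf_commands(prev, seg.aperture):
                        t_cmd = t_off + mv.command_rank * params.interleaf_delay
                        tag = f"pair {mv.pair_index} {mv.bank}"
                        events.append(
                            DeliveryEvent(t_cmd, head, "leaf_command", tag)
                        )
                        events.append(
                            DeliveryEvent(
                                t_cmd + mv.distance / params.leaf_speed,
                                head,
                                "leaf_arrival",
                                tag,
                            )
                        )
                    t = t_off + transition_time(prev, seg.aperture, params)
                on_s = (
                    beam_on_time(seg.beam_on_time_min, dr, calibration.nominal_dose_rate)
                    * 60.0
                )
                events.append(DeliveryEvent(t, head, "beam_on", f"segment {si + 1}"))
                t += on_s
                events.append(DeliveryEvent(t, head, "beam_off", f"segment {si + 1}"))
            head_ends.append(t)
            last_aperture[beam.head] = beam.segments[-1].aperture
        group_end = max(head_ends)
        if gi < len(ordered) - 1:
            nxt = ordered[gi + 1]
            rot = predict_rotation_time(diffs[gi], params)
            events.append(
                DeliveryEvent(
                    group_end,
                    "gantry",
                    "rotation_start",
                    f"{group.gantry_angle:g} -> {nxt.gantry_angle:g} deg",
                )
            )
            events.append(
                DeliveryEvent(
                    group_end + rot,
                    "gantry",
                    "rotation_end",
                    f"at {nxt.gantry_angle:g} deg",
                )
            )
            # first-segment apertures form during rotation; flag a would-be race
            for beam in nxt.beams:
                prev_ap = last_aperture.get(beam.head)
                if prev_ap is None:
                    continue
                travel = transition_time(prev_ap, beam.segments[0].aperture, params)
                if travel > rot:
                    warnings.warn(
                        f"head {beam.head}: leaf travel into group at "
                        f"{nxt.gantry_angle:g} deg needs {travel:.2f} s but the "
                        f"rotation allows {rot:.2f} s",
                        stacklevel=2,
                    )
            group_start = group_end + rot

    events.sort(key=lambda e: (e.time_s, _TIE_ORDER[e.kind], e.head))
    return events, group_end


def export_timeline(events: list[DeliveryEvent], path: str | Path) -> None:
    """Write events as CSV (columns time_s, head, kind, detail).

    Times are rendered with ``repr`` so the file parses back bit-exactly.
    """
    with open(path, "w") as fh:
        fh.write("time_s,head,kind,detail\n")
        for e in events:
            fh.write(f"{e.time_s!r},{e.head},{e.kind},{e.detail}\n")


def read_timeline(path: str | Path) -> list[DeliveryEvent]:
    df = pd.read_csv(
        path,
        keep_default_na=False,
        dtype={"head": str, "detail": str},
        float_precision="round_trip",
    )
    return [
        DeliveryEvent(float(r.time_s), str(r.head), str(r.kind), str(r.detail))
        for r in df.itertuples(index=False)
    ]
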