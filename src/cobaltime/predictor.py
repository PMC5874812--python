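"""Closed-form total delivery-time prediction and duty cycles.

Total delivery time is the sum of four components:

    T_total = T_initial + T_gantry_total
              + sum_g T_beam_on(b_g) + sum_g T_MLC(b_g)

where the sums run over beam groups and ``b_g`` is the group's *dominant*
beam — the one with the largest decay-corrected beam-on plus MLC motion
time.  The three heads of a group fire simultaneously and independently,
so only the last-finishing head contributes wall-clock.

Initialization (rotating from the previous patient's final gantry angle to
this plan's first group, plus checks) depends on where the previous
treatment happened to end and is treated as a constant: the mean of logged
initialization times when a delivery record is supplied, else the fitted
default.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

from .errors import DomainError
from .gantry_model import predict_rotation_time, reorder_groups
from .mlc_model import beam_mlc_time
from .plan_model import (
    BeamGroup,
    DeliveryRecord,
    SourceCalibration,
    TimingParams,
    TreatmentPlan,
)
from .source_decay import beam_on_time, dose_rate_on

__all__ = [
    "PredictionReport",
    "initialization_time",
    "dominant_beam",
    "predict",
    "render_report",
]


@dataclass
class PredictionReport:
    """Component breakdown of a predicted delivery, all times in minutes.

    ``t_total_min`` is exactly the sum of the four components (no hidden
    terms).  ``duty_cycle_per_beam`` holds, per group in delivery order, a
    mapping from head index to that beam's own beam-on/(beam-on + MLC)
    fraction; ``overall_duty_cycle`` is dominant-beam beam-on time over
    total time.
    """

    t_initial_min: float
    t_beam_on_min: float
    t_gantry_min: float
    t_mlc_min: float
    t_total_min: float
    dominant_beam_per_group: tuple[int, ...] = ()
    group_angles: tuple[float, ...] = ()
    duty_cycle_per_beam: tuple[dict[int, float], ...] = ()
    overall_duty_cycle: float = float("nan")

    @classmethod
    def from_components(
        cls,
        t_initial_min: float,
        t_beam_on_min: float,
        t_gantry_min: float,
        t_mlc_min: float,
    ) -> "PredictionReport":
        """Assemble a report from the four component times alone."""
        total = t_initial_min + t_beam_on_min + t_gantry_min + t_mlc_min
        return cls(
            t_initial_min=t_initial_min,
            t_beam_on_min=t_beam_on_min,
            t_gantry_min=t_gantry_min,
            t_mlc_min=t_mlc_min,
            t_total_min=total,
            overall_duty_cycle=t_beam_on_min / total,
        )

    def to_dict(self) -> dict:
        return {
            "t_initial_min": self.t_initial_min,
            "t_beam_on_min": self.t_beam_on_min,
            "t_gantry_min": self.t_gantry_min,
            "t_mlc_min": self.t_mlc_min,
            "t_total_min": self.t_total_min,
            "dominant_beam_per_group": list(self.dominant_beam_per_group),
            "group_angles": list(self.group_angles),
            "duty_cycle_per_beam": [
                {str(h): d for h, d in g.items()} for g in self.duty_cycle_per_beam
            ],
            "overall_duty_cycle": self.overall_duty_cycle,
        }


def initialization_time(
    records: DeliveryRecord | None, params: TimingParams
) -> float:
    """Initialization overhead estimate in seconds.

    Mean of recorded initialization times when records are supplied,
    otherwise the fitted constant in ``params``.
    """
    if records is None:
        return params.t_initial
    if not records.initialization_time_s:
        raise DomainError("delivery records contain no initialization times")
    times = records.initialization_time_s
    return sum(times) / len(times)


def _beam_load_s(
    beam, calibration: SourceCalibration, treatment_date: dt.date, params: TimingParams
) -> tuple[float, float]:
    """(decay-corrected beam-on seconds, MLC motion seconds) for one beam."""
    dr = dose_rate_on(calibration, beam.head, treatment_date)
    on_min = beam_on_time(beam.planned_beam_on_min, dr, calibration.nominal_dose_rate)
    return on_min * 60.0, beam_mlc_time(beam, params)


def dominant_beam(
    group: BeamGroup,
    calibration: SourceCalibration,
    treatment_date: dt.date,
    params: TimingParams,
) -> int:
    """Head index of the group's last-finishing beam: the one maximizing
    beam-on + MLC time.  Ties resolve to the lowest head index."""
    best_head, best_load = None, -1.0
    for beam in group.beams:  # beams are stored sorted by head
        on_s, mlc_s = _beam_load_s(beam, calibration, treatment_date, params)
        load = on_s + mlc_s
        if load > best_load:
            best_head, best_load = beam.head, load
    return best_head


def predict(
    plan: TreatmentPlan,
    calibration: SourceCalibration,
    treatment_date: dt.date,
    params: TimingParams | None = None,
    records: DeliveryRecord | None = None,
) -> PredictionReport:
    """Predict the total delivery time of ``plan`` on ``treatment_date``."""
    if params is None:
        params = TimingParams()
    t_init_s = initialization_time(records, params)
    ordered, diffs = reorder_groups(plan)
    t_gantry_s = sum(predict_rotation_time(d, params) for d in diffs)

    t_on_s = 0.0
    t_mlc_s = 0.0
    dominants: list[int] = []
    duties: list[dict[int, float]] = []
    for group in ordered:
        best_head, best_on, best_mlc, best_load = None, 0.0, 0.0, -1.0
        group_duty: dict[int, float] = {}
        for beam in group.beams:
            on_s, mlc_s = _beam_load_s(beam, calibration, treatment_date, params)
            group_duty[beam.head] = on_s / (on_s + mlc_s)
            if on_s + mlc_s > best_load:
                best_head, best_on, best_mlc = beam.head, on_s, mlc_s
                best_load = on_s + mlc_s
        t_on_s += best_on
        t_mlc_s += best_mlc
        dominants.append(best_head)
        duties.append(group_duty)

    t_initial_min = t_init_s / 60.0
    t_beam_on_min = t_on_s / 60.0
    t_gantry_min = t_gantry_s / 60.0
    t_mlc_min = t_mlc_s / 60.0
    t_total_min = t_initial_min + t_beam_on_min + t_gantry_min + t_mlc_min
    return PredictionReport(
        t_initial_min=t_initial_min,
        t_beam_on_min=t_beam_on_min,
        t_gantry_min=t_gantry_min,
        t_mlc_min=t_mlc_min,
        t_total_min=t_total_min,
        dominant_beam_per_group=tuple(dominants),
        group_angles=tuple(g.gantry_angle for g in ordered),
        duty_cycle_per_beam=tuple(duties),
        overall_duty_cycle=t_beam_on_min / t_total_min,
    )


def render_report(report: PredictionReport) -> str:
    """Human-readable component table, minutes to 4 decimals."""
    lines = [
        "component            minutes",
        f"initialization      {report.t_initial_min:8.4f}",
        f"beam-on (dominant)  {report.t_beam_on_min:8.4f}",
        f"gantry rotation     {report.t_gantry_min:8.4f}",
        f"MLC motion          {report.t_mlc_min:8.4f}",
        f"total               {report.t_total_min:8.4f}",
    ]
    if report.dominant_beam_per_group:
        pairs = ", ".join(
            f"{a:.1f} deg -> head {h}"
            for a, h in zip(report.group_angles, report.dominant_beam_per_group)
        )
        lines.append(f"dominant beams: {pairs}")
    if report.overall_duty_cycle == report.overall_duty_cycle:  # not NaN
        lines.append(f"overall duty cycle: {report.overall_duty_cycle:.4f}")
    return "\n".join(lines)
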