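"""Plan-complexity metrics: beam modulation, plan modulation, duty cycle.

Beam modulation (BM) measures how far a beam's dose is delivered through
small sub-apertures rather than its full composite field:

    BM = 1 - sum_s(t_s * A_s) / (t_beam * A_union)

where ``A_s`` is segment s's aperture area, ``t_s`` its planned beam-on
time, and ``A_union`` the area of the union of all the beam's apertures
(computed exactly per leaf pair as a union of intervals).  BM is 0 for a
single static field and approaches 1 as the field is shredded into many
brief small segments.  Plan modulation (PM) is the beam-on-time-weighted
mean of BM over beams, with times normalized to a 2 Gy fraction.

Higher modulation means more segment transitions per delivered monitor
unit, hence a lower duty cycle (beam-on fraction of wall-clock) and a
longer total delivery time; ``complexity_time_relation`` quantifies that
tendency over a family of plans with Spearman rank correlations.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .plan_model import (
    CLOSED_GAP_TOL,
    N_LEAF_PAIRS,
    Beam,
    MLCAperture,
    SourceCalibration,
    TimingParams,
    TreatmentPlan,
)
from .predictor import predict

__all__ = [
    "DEFAULT_LEAF_WIDTH",
    "ComplexityReport",
    "ComplexityRelation",
    "aperture_area",
    "union_area",
    "beam_modulation",
    "plan_modulation",
    "plan_complexity_report",
    "complexity_time_relation",
]

#: Projected leaf width at isocenter, cm.  Exposed because the machine's
#: value is configuration, not physics; it scales all areas uniformly and
#: cancels in BM only for single-pair fields, so it stays explicit.
DEFAULT_LEAF_WIDTH = 1.05

REFERENCE_FRACTION_DOSE_GY = 2.0


def aperture_area(
    aperture: MLCAperture,
    leaf_width: float = DEFAULT_LEAF_WIDTH,
    gap_tol: float = CLOSED_GAP_TOL,
) -> float:
    """Open area (cm^2) of one aperture; closed pairs contribute nothing."""
    if not leaf_width > 0:
        raise DomainError(f"leaf_width must be > 0, got {leaf_width}")
    # accumulate pair by pair, mirroring union_area's order, so that a
    # single-segment beam has area exactly equal to its union area
    total = 0.0
    for left, right in zip(aperture.left, aperture.right):
        if right - left > gap_tol:
            total += right - left
    return total * leaf_width


def _union_length(intervals: list[tuple[float, float]]) -> float:
    """Total measure of a union of 1-D intervals."""
    if not intervals:
        return 0.0
    intervals = sorted(intervals)
    total = 0.0
    lo, hi = intervals[0]
    for a, b in intervals[1:]:
        if a > hi:
            total += hi - lo
            lo, hi = a, b
        else:
            hi = max(hi, b)
    return total + (hi - lo)


def union_area(
    apertures: list[MLCAperture],
    leaf_width: float = DEFAULT_LEAF_WIDTH,
    gap_tol: float = CLOSED_GAP_TOL,
) -> float:
    """Area (cm^2) of the union of apertures, exact per leaf pair."""
    if not leaf_width > 0:
        raise DomainError(f"leaf_width must be > 0, got {leaf_width}")
    total = 0.0
    for pair in range(N_LEAF_PAIRS):
        intervals = [
            (ap.left[pair], ap.right[pair])
            for ap in apertures
            if ap.right[pair] - ap.left[pair] > gap_tol
        ]
        total += _union_length(intervals)
    return total * leaf_width


def beam_modulation(
    beam: Beam,
    leaf_width: float = DEFAULT_LEAF_WIDTH,
    gap_tol: float = CLOSED_GAP_TOL,
) -> float:
    """BM in [0, 1); 0 iff every segment opens the full composite field."""
    a_union = union_area([s.aperture for s in beam.segments], leaf_width, gap_tol)
    if a_union <= 0.0:
        raise DomainError("empty beam: union aperture area is zero")
    t_total = beam.planned_beam_on_min
    weighted = sum(
        s.beam_on_time_min * aperture_area(s.aperture, leaf_width, gap_tol)
        for s in beam.segments
    )
    # clamp float residue when every segment equals the union field
    return max(0.0, 1.0 - weighted / (t_total * a_union))


def plan_modulation(
    plan: TreatmentPlan,
    leaf_width: float = DEFAULT_LEAF_WIDTH,
    gap_tol: float = CLOSED_GAP_TOL,
) -> float:
    """Beam-on-time-weighted mean BM, times normalized to a 2 Gy fraction.

    Within one plan the 2 Gy normalization rescales every weight by the
    same factor, so it matters only when aggregating across plans; it is
    kept in the weights for symmetry with that use.
    """
    scale = REFERENCE_FRACTION_DOSE_GY / plan.prescription_dose_per_fraction
    num = 0.0
    den = 0.0
    for _, beam in plan.iter_beams():
        w = beam.planned_beam_on_min * scale
        num += w * beam_modulation(beam, leaf_width, gap_tol)
        den += w
    return num / den


@dataclass(frozen=True)
class ComplexityReport:
    """Per-plan complexity summary."""

    plan_id: str
    bm_per_beam: tuple[float, ...]
    pm: float
    duty_cycle_overall: float
    total_time_normalized_min: float  # predicted total scaled to a 2 Gy fraction


def plan_complexity_report(
    plan: TreatmentPlan,
    calibration: SourceCalibration,
    treatment_date: dt.date,
    params: TimingParams | None = None,
    leaf_width: float = DEFAULT_LEAF_WIDTH,
) -> ComplexityReport:
    report = predict(plan, calibration, treatment_date, params)
    scale = REFERENCE_FRACTION_DOSE_GY / plan.prescription_dose_per_fraction
    return ComplexityReport(
        plan_id=plan.plan_id,
        bm_per_beam=tuple(
            beam_modulation(b, leaf_width) for _, b in plan.iter_beams()
        ),
        pm=plan_modulation(plan, leaf_width),
        duty_cycle_overall=report.overall_duty_cycle,
        total_time_normalized_min=report.t_total_min * scale,
    )


@dataclass(frozen=True)
class ComplexityRelation:
    """Complexity-vs-time summary over a family of plans.

    ``rho_pm_duty`` and ``rho_pm_time`` are Spearman rank correlations of
    PM with overall duty cycle and with normalized total time; they are
    NaN (and ``degenerate`` is True) when either variable has no variance.
    """

    table: pd.DataFrame
    rho_pm_duty: float
    rho_pm_time: float
    degenerate: bool


def complexity_time_relation(
    plans: list[TreatmentPlan],
    calibration: SourceCalibration,
    treatment_date: dt.date,
    params: TimingParams | None = None,
    leaf_width: float = DEFAULT_LEAF_WIDTH,
) -> ComplexityRelation:
    """Tabulate (PM, duty cycle, normalized time) per plan and correlate."""
    if len(plans) < 3:
        raise DomainError(f"need >= 3 plans to correlate, got {len(plans)}")
    rows = [
        plan_complexity_report(p, calibration, treatment_date, params, leaf_width)
        for p in plans
    ]
    table = pd.DataFrame(
        {
            "plan_id": [r.plan_id for r in rows],
            "pm": [r.pm for r in rows],
            "duty_cycle": [r.duty_cycle_overall for r in rows],
            "total_time_normalized_min": [r.total_time_normalized_min for r in rows],
        }
    )
    pm = table["pm"].to_numpy()
    degenerate = (
        np.ptp(pm) == 0.0
        or np.ptp(table["duty_cycle"].to_numpy()) == 0.0
        or np.ptp(table["total_time_normalized_min"].to_numpy()) == 0.0
    )
    if degenerate:
        rho_duty = rho_time = float("nan")
    else:
        rho_duty = float(stats.spearmanr(pm, table["duty_cycle"]).statistic)
        rho_time = float(
            stats.spearmanr(pm, table["total_time_normalized_min"]).statistic
        )
    return ComplexityRelation(
        table=table,
        rho_pm_duty=rho_duty,
        rho_pm_time=rho_time,
        degenerate=degenerate,
    )
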