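"""Gantry sequencing and the rotation-time regression.

At delivery the machine reorders the planned beam groups by gantry angle so
the gantry sweeps monotonically in one direction instead of rotating back
and forth.  The wall-clock cost of each inter-group rotation is affine in
the swept angle,

    T_G = beta0 + beta1 * theta_diff,

with (beta0, beta1) fitted by ordinary least squares to (angle difference,
rotation time) pairs mined from delivery logs.  Because reversing the sweep
direction leaves the consecutive angle differences unchanged, predicted
rotation time is independent of direction; ascending order is used as the
canonical order here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import DomainError, PlanValidationError
from .plan_model import BeamGroup, DeliveryRecord, TimingParams, TreatmentPlan

__all__ = [
    "RegressionFit",
    "reorder_groups",
    "fit_rotation_regression",
    "predict_rotation_time",
    "total_gantry_time",
    "apply_fit",
]


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of rotation time (s) on gantry angle difference (deg)."""

    beta0: float
    beta1: float
    r_squared: float
    n_points: int
    beta0_stderr: float = float("nan")
    beta1_stderr: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise DomainError(f"regression needs >= 2 points, got {self.n_points}")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise DomainError(f"r_squared out of [0, 1]: {self.r_squared}")


def reorder_groups(plan: TreatmentPlan) -> tuple[list[BeamGroup], list[float]]:
    """Sort groups into the canonical ascending sweep; return them with the
    N_g - 1 consecutive angle differences (deg, each > 0).

    The final-to-first wrap gap is never traversed: a treatment sweeps its
    angular span once and stops.
    """
    angles = [g.gantry_angle for g in plan.groups]
    if len(set(angles)) != len(angles):
        raise PlanValidationError(f"duplicate group gantry angles: {angles}")
    ordered = sorted(plan.groups, key=lambda g: g.gantry_angle)
    diffs = [
        b.gantry_angle - a.gantry_angle for a, b in zip(ordered, ordered[1:])
    ]
    return ordered, diffs


def fit_rotation_regression(records: DeliveryRecord) -> RegressionFit:
    """Fit the rotation-time line by ordinary least squares."""
    x = np.asarray(records.angle_diff_deg, dtype=float)
    y = np.asarray(records.rotation_time_s, dtype=float)
    if x.size < 2:
        raise DomainError(f"regression needs >= 2 records, got {x.size}")
    if np.ptp(x) == 0.0:
        raise DomainError("degenerate design: all angle differences identical")
    res = stats.linregress(x, y)
    r2 = min(float(res.rvalue) ** 2, 1.0)
    return RegressionFit(
        beta0=float(res.intercept),
        beta1=float(res.slope),
        r_squared=r2,
        n_points=int(x.size),
        beta0_stderr=float(res.intercept_stderr),
        beta1_stderr=float(res.stderr),
    )


def predict_rotation_time(theta_diff: float, params: TimingParams) -> float:
    """Predicted rotation time (s) to sweep ``theta_diff`` degrees."""
    if not 0.0 < theta_diff < 360.0:
        raise DomainError(f"theta_diff must lie in (0, 360), got {theta_diff}")
    return params.beta0 + params.beta1 * theta_diff


def total_gantry_time(plan: TreatmentPlan, params: TimingParams) -> float:
    """Total predicted rotation time (s) over the reordered sweep; 0 for a
    single-group plan.  Invariant under any permutation of the input
    groups."""
    _, diffs = reorder_groups(plan)
    return sum(predict_rotation_time(d, params) for d in diffs)


def apply_fit(fit: RegressionFit, params: TimingParams | None = None) -> TimingParams:
    """Return ``params`` (defaults if None) with the fitted line patched in."""
    base = params if params is not None else TimingParams()
    return replace(base, beta0=fit.beta0, beta1=fit.beta1)
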