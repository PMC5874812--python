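"""Cobalt-60 source decay and decay-corrected beam-on time.

Planned beam-on times assume the nominal 1.85 Gy/min planning dose rate.
On any later treatment day the sources have decayed, so the machine must
hold each segment open longer to deliver the planned dose-time product:

    DR(j)      = DR_ref(j) * (1/2) ** (n_days / HL)
    T_beam_on  = T_planned * DR_nominal / DR(j)

with ``n_days`` the (possibly fractional) day count between calibration
and treatment and ``HL`` the half-life in days.
"""

from __future__ import annotations

import datetime as dt

from .errors import DomainError
from .plan_model import SourceCalibration

__all__ = ["days_between", "dose_rate_on", "beam_on_time"]


def days_between(reference: dt.date, treatment: dt.date) -> float:
    """Day count from ``reference`` to ``treatment``, fractional if either
    carries a time of day."""
    ref = reference if isinstance(reference, dt.datetime) else dt.datetime.combine(reference, dt.time())
    tre = treatment if isinstance(treatment, dt.datetime) else dt.datetime.combine(treatment, dt.time())
    return (tre - ref).total_seconds() / 86400.0


def dose_rate_on(
    calibration: SourceCalibration, head: int, treatment_date: dt.date
) -> float:
    """Decayed dose rate (Gy/min) of ``head`` on ``treatment_date``.

    Raises :class:`DomainError` if the treatment date precedes the
    calibration date — the model never extrapolates to a stronger source.
    """
    if head not in calibration.reference_dose_rate:
        raise DomainError(f"calibration has no dose rate for head {head}")
    n_days = days_between(calibration.reference_date, treatment_date)
    if n_days < 0:
        raise DomainError(
            f"treatment date {treatment_date} precedes calibration date "
            f"{calibration.reference_date}"
        )
    return calibration.reference_dose_rate[head] * 0.5 ** (
        n_days / calibration.half_life_days
    )


def beam_on_time(
    planned_beam_on_min: float, dose_rate: float, nominal_dose_rate: float
) -> float:
    """Actual beam-on time (minutes) for a planned beam-on time (minutes).

    Scales the planned time by nominal/actual dose rate so the delivered
    dose-rate x time product is conserved.
    """
    if not planned_beam_on_min > 0:
        raise DomainError(f"planned beam-on time must be > 0, got {planned_beam_on_min}")
    if not dose_rate > 0:
        raise DomainError(f"dose rate must be > 0, got {dose_rate}")
    if not nominal_dose_rate > 0:
        raise DomainError(f"nominal dose rate must be > 0, got {nominal_dose_rate}")
    return planned_beam_on_min * nominal_dose_rate / dose_rate
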