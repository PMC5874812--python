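"""Shared fixtures: a calibration, dates, and small hand-built plans."""

from __future__ import annotations

import datetime as dt

import pytest

from cobaltime import (
    Beam,
    BeamGroup,
    MLCAperture,
    N_LEAF_PAIRS,
    Segment,
    SourceCalibration,
    TimingParams,
    TreatmentPlan,
)


@pytest.fixture
def calibration() -> SourceCalibration:
    return SourceCalibration(
        reference_dose_rate={1: 1.55, 2: 1.54, 3: 1.56},
        reference_date=dt.date(2026, 1, 1),
    )


@pytest.fixture
def treatment_date() -> dt.date:
    return dt.date(2026, 6, 1)


@pytest.fixture
def params() -> TimingParams:
    return TimingParams()


def make_aperture(
    open_pairs: dict[int, tuple[float, float]] | None = None,
    parked_at: float = 0.0,
) -> MLCAperture:
    """Aperture closed at ``parked_at`` except for 0-based ``open_pairs``
    mapping pair index -> (left, right)."""
    left = [parked_at] * N_LEAF_PAIRS
    right = [parked_at] * N_LEAF_PAIRS
    for idx, (l, r) in (open_pairs or {}).items():
        left[idx], right[idx] = l, r
    return MLCAperture(left=tuple(left), right=tuple(right))


def make_beam(
    apertures: list[MLCAperture],
    beam_on_min: float | list[float] = 1.0,
    head: int = 1,
    angle: float = 90.0,
) -> Beam:
    times = (
        [beam_on_min] * len(apertures)
        if isinstance(beam_on_min, (int, float))
        else list(beam_on_min)
    )
    return Beam(
        head=head,
        gantry_angle=angle,
        segments=tuple(
            Segment(aperture=a, beam_on_time_min=t) for a, t in zip(apertures, times)
        ),
    )


def single_beam_plan(
    beam: Beam, group_angle: float | None = None, dose_gy: float = 2.0
) -> TreatmentPlan:
    angle = beam.gantry_angle if group_angle is None else group_angle
    return TreatmentPlan(
        plan_id="test",
        prescription_dose_per_fraction=dose_gy,
        groups=(BeamGroup(gantry_angle=angle, beams=(beam,)),),
    )
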