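"""Domain types and file formats for step-and-shoot cobalt-60 treatment plans.

The delivery system modeled here has three cobalt-60 heads mounted 120
degrees apart on a ring gantry.  A treatment plan is a list of *beam
groups* (gantry positions); each group carries one beam per participating
head, and each beam is a sequence of *segments* — an MLC aperture of 30
leaf pairs plus a beam-on time planned at the nominal dose rate.

Plans are serialized to a small documented JSON format, delivery records
(gantry-rotation and initialization timings harvested from machine logs)
to plain CSV, and source calibrations to YAML/JSON.  All angles are in
degrees on the half-open interval [0, 360); leaf positions are in cm
projected to isocenter; times inside the data model keep the units stated
on each field (beam-on times in minutes, everything machine-level in
seconds).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, PlanValidationError

__all__ = [
    "N_LEAF_PAIRS",
    "CLOSED_GAP_TOL",
    "NOMINAL_DOSE_RATE",
    "DEFAULT_HALF_LIFE_DAYS",
    "HEAD_ANGLE_RANGES",
    "MLCAperture",
    "Segment",
    "Beam",
    "BeamGroup",
    "TreatmentPlan",
    "SourceCalibration",
    "TimingParams",
    "DeliveryRecord",
    "angle_in_head_range",
    "read_plan",
    "write_plan",
    "read_delivery_records",
    "write_delivery_records",
    "read_calibration",
    "write_calibration",
    "read_params",
    "write_params",
]

#: Number of opposed leaf pairs in the MLC (60 leaves total).
N_LEAF_PAIRS = 30

#: A pair whose gap (right - left) is at or below this tolerance (cm) is
#: treated as *closed*: it contributes nothing to the aperture.  The small
#: positive value absorbs rounding in exported plans.
CLOSED_GAP_TOL = 0.05

#: Planning-stage dose rate (Gy/min) assumed for every head at new-source
#: strength; planned beam-on times refer to this rate.
NOMINAL_DOSE_RATE = 1.85

#: Cobalt-60 half-life of 5.25 years expressed in days.
DEFAULT_HALF_LIFE_DAYS = 5.25 * 365.25

#: Reachable gantry arc per head, degrees (lo, hi); head 3 wraps through 0.
HEAD_ANGLE_RANGES: dict[int, tuple[float, float]] = {
    1: (30.0, 150.0),
    2: (150.0, 270.0),
    3: (270.0, 30.0),
}

_ANGLE_TOL = 1e-6


def angle_in_head_range(head: int, angle_deg: float) -> bool:
    """True if ``angle_deg`` lies on head ``head``'s reachable arc."""
    lo, hi = HEAD_ANGLE_RANGES[head]
    a = angle_deg % 360.0
    if lo <= hi:
        return lo - _ANGLE_TOL <= a <= hi + _ANGLE_TOL
    return a >= lo - _ANGLE_TOL or a <= hi + _ANGLE_TOL


def _as_float_tuple(values: Sequence[float], what: str) -> tuple[float, ...]:
    try:
        return tuple(float(v) for v in values)
    except (TypeError, ValueError) as exc:
        raise PlanValidationError(f"{what}: expected a sequence of numbers") from exc


@dataclass(frozen=True)
class MLCAperture:
    """One MLC-shaped field: 30 opposed (left, right) leaf positions in cm.

    The left bank projects from negative x, the right bank from positive x;
    for every pair the left position must not exceed the right position.
    """

    left: tuple[float, ...]
    right: tuple[float, ...]

    def __post_init__(self) -> None:
        left = _as_float_tuple(self.left, "mlc.left")
        right = _as_float_tuple(self.right, "mlc.right")
        if len(left) != N_LEAF_PAIRS:
            raise PlanValidationError(
                f"mlc.left: expected {N_LEAF_PAIRS} leaf positions, got {len(left)}"
            )
        if len(right) != N_LEAF_PAIRS:
            raise PlanValidationError(
                f"mlc.right: expected {N_LEAF_PAIRS} leaf positions, got {len(right)}"
            )
        for i, (l, r) in enumerate(zip(left, right), start=1):
            if l > r:
                raise PlanValidationError(
                    f"mlc pair {i}: left position {l} exceeds right position {r}"
                )
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)

    def gaps(self) -> np.ndarray:
        """Per-pair opening (right - left), cm; always >= 0."""
        return np.asarray(self.right) - np.asarray(self.left)

    def closed_pairs(self, gap_tol: float = CLOSED_GAP_TOL) -> np.ndarray:
        """Boolean mask over pairs whose gap is within ``gap_tol``."""
        return self.gaps() <= gap_tol


@dataclass(frozen=True)
class Segment:
    """One step-and-shoot segment: an aperture held for a beam-on time.

    ``beam_on_time_min`` is in minutes at the nominal planning dose rate.
    """

    aperture: MLCAperture
    beam_on_time_min: float

    def __post_init__(self) -> None:
        if not self.beam_on_time_min > 0:
            raise PlanValidationError(
                f"segment beam_on_time_min must be > 0, got {self.beam_on_time_min}"
            )


@dataclass(frozen=True)
class Beam:
    """All segments delivered by one head at one gantry position."""

    head: int
    gantry_angle: float
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if self.head not in (1, 2, 3):
            raise PlanValidationError(f"beam head must be 1, 2, or 3, got {self.head}")
        if not 0.0 <= self.gantry_angle < 360.0:
            raise PlanValidationError(
                f"beam gantry_angle must lie in [0, 360), got {self.gantry_angle}"
            )
        if not angle_in_head_range(self.head, self.gantry_angle):
            lo, hi = HEAD_ANGLE_RANGES[self.head]
            raise DomainError(
                f"gantry angle {self.gantry_angle} deg is outside head "
                f"{self.head}'s arc [{lo}, {hi}] deg"
            )
        segments = tuple(self.segments)
        if len(segments) < 1:
            raise PlanValidationError("beam must contain at least one segment")
        object.__setattr__(self, "segments", segments)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def planned_beam_on_min(self) -> float:
        """Total planned beam-on time (minutes at nominal dose rate)."""
        return sum(s.beam_on_time_min for s in self.segments)


@dataclass(frozen=True)
class BeamGroup:
    """Beams deliverable simultaneously: one gantry position, up to 3 heads.

    Member beams sit 120 degrees apart (mod 360) so that all three heads can
    face their planned directions at once; ``gantry_angle`` is the group's
    canonical angle used for ordering and rotation arithmetic.
    """

    gantry_angle: float
    beams: tuple[Beam, ...]

    def __post_init__(self) -> None:
        beams = tuple(self.beams)
        if not 1 <= len(beams) <= 3:
            raise PlanValidationError(
                f"beam group must contain 1-3 beams, got {len(beams)}"
            )
        heads = [b.head for b in beams]
        if len(set(heads)) != len(heads):
            raise PlanValidationError(
                f"beam group at {self.gantry_angle} deg repeats a head: {heads}"
            )
        for b in beams:
            off = (b.gantry_angle - self.gantry_angle) % 120.0
            if min(off, 120.0 - off) > _ANGLE_TOL:
                raise PlanValidationError(
                    f"beam on head {b.head} at {b.gantry_angle} deg is not a "
                    f"multiple of 120 deg from group angle {self.gantry_angle}"
                )
        for i, a in enumerate(beams):
            for b in beams[i + 1 :]:
                d = (a.gantry_angle - b.gantry_angle) % 360.0
                if min(abs(d - 120.0), abs(d - 240.0)) > _ANGLE_TOL:
                    raise PlanValidationError(
                        f"beams on heads {a.head} and {b.head} are {d} deg apart; "
                        "beams of one group must be 120 deg apart (mod 360)"
                    )
        object.__setattr__(self, "beams", tuple(sorted(beams, key=lambda b: b.head)))


@dataclass(frozen=True)
class TreatmentPlan:
    plan_id: str
    prescription_dose_per_fraction: float
    groups: tuple[BeamGroup, ...]

    def __post_init__(self) -> None:
        groups = tuple(self.groups)
        if len(groups) < 1:
            raise PlanValidationError("plan must contain at least one beam group")
        if not self.prescription_dose_per_fraction > 0:
            raise PlanValidationError(
                "prescription_dose_per_fraction must be > 0, got "
                f"{self.prescription_dose_per_fraction}"
            )
        angles = [g.gantry_angle for g in groups]
        if len(set(angles)) != len(angles):
            raise PlanValidationError(
                f"group gantry angles must be distinct, got {angles}"
            )
        object.__setattr__(self, "groups", groups)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def iter_beams(self) -> Iterator[tuple[BeamGroup, Beam]]:
        for g in self.groups:
            for b in g.beams:
                yield g, b


@dataclass(frozen=True)
class SourceCalibration:
    """Per-head reference dose rates at a calibration date.

    ``reference_dose_rate`` maps head index (1..3) to the measured dose rate
    in Gy/min on ``reference_date``.  ``half_life_days`` governs the decay
    of all three sources.
    """

    reference_dose_rate: Mapping[int, float]
    reference_date: dt.date
    half_life_days: float = DEFAULT_HALF_LIFE_DAYS
    nominal_dose_rate: float = NOMINAL_DOSE_RATE

    def __post_init__(self) -> None:
        rates = {int(k): float(v) for k, v in dict(self.reference_dose_rate).items()}
        if set(rates) != {1, 2, 3}:
            raise PlanValidationError(
                f"calibration must give dose rates for heads 1, 2, 3; got {sorted(rates)}"
            )
        for head, rate in rates.items():
            if not rate > 0:
                raise PlanValidationError(
                    f"calibration head {head}: dose rate must be > 0, got {rate}"
                )
        if not self.half_life_days > 0:
            raise PlanValidationError(
                f"half_life_days must be > 0, got {self.half_life_days}"
            )
        if not self.nominal_dose_rate > 0:
            raise PlanValidationError(
                f"nominal_dose_rate must be > 0, got {self.nominal_dose_rate}"
            )
        object.__setattr__(self, "reference_dose_rate", rates)


@dataclass(frozen=True)
class TimingParams:
    """The fitted machine-timing constants of the delivery-time model.

    Defaults are the values established for the modeled machine:

    - ``t_initial``: mean pre-first-beam overhead, s
    - ``beta0``, ``beta1``: gantry rotation-time regression intercept (s)
      and slope (s/deg)
    - ``mlc_overall_delay``: fixed per-transition latency covering the
      source off/on end effect and control-system delays, s
    - ``interleaf_delay``: per-leaf command latency (one command at a
      time), s
    - ``leaf_speed``: MLC leaf speed, cm/s
    """

    t_initial: float = 27.7
    beta0: float = 3.61
    beta1: float = 0.24
    mlc_overall_delay: float = 2.2
    interleaf_delay: float = 0.034
    leaf_speed: float = 2.1

    def __post_init__(self) -> None:
        for name in (
            "t_initial",
            "beta0",
            "beta1",
            "mlc_overall_delay",
            "interleaf_delay",
            "leaf_speed",
        ):
            value = getattr(self, name)
            if not value > 0:
                raise PlanValidationError(f"timing parameter {name} must be > 0, got {value}")


@dataclass(frozen=True)
class DeliveryRecord:
    """Timings harvested from delivery logs, used to fit TimingParams.

    ``angle_diff_deg[i]`` is the gantry angle swept between two consecutive
    beam groups of some recorded treatment and ``rotation_time_s[i]`` the
    wall-clock the rotation took; ``initialization_time_s`` holds one
    pre-first-beam overhead per recorded treatment.
    """

    angle_diff_deg: tuple[float, ...]
    rotation_time_s: tuple[float, ...]
    initialization_time_s: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        angles = _as_float_tuple(self.angle_diff_deg, "angle_diff_deg")
        times = _as_float_tuple(self.rotation_time_s, "rotation_time_s")
        inits = _as_float_tuple(self.initialization_time_s, "initialization_time_s")
        if len(angles) != len(times):
            raise PlanValidationError(
                f"angle_diff_deg has {len(angles)} rows but rotation_time_s has {len(times)}"
            )
        for i, a in enumerate(angles):
            if not 0.0 < a < 360.0:
                raise PlanValidationError(
                    f"angle_diff_deg[{i}]: must lie in (0, 360), got {a}"
                )
        for i, t in enumerate(times):
            if not t > 0:
                raise PlanValidationError(
                    f"rotation_time_s[{i}]: must be > 0, got {t}"
                )
        for i, t in enumerate(inits):
            if not t > 0:
                raise PlanValidationError(
                    f"initialization_time_s[{i}]: must be > 0, got {t}"
                )
        object.__setattr__(self, "angle_diff_deg", angles)
        object.__setattr__(self, "rotation_time_s", times)
        object.__setattr__(self, "initialization_time_s", inits)

    @property
    def n_rows(self) -> int:
        return len(self.angle_diff_deg)


# ---------------------------------------------------------------------------
# Plan JSON
# ---------------------------------------------------------------------------


def _segment_from_dict(d: dict, where: str) -> Segment:
    try:
        mlc = d["mlc"]
        aperture = MLCAperture(left=mlc["left"], right=mlc["right"])
        return Segment(aperture=aperture, beam_on_time_min=float(d["beam_on_time_min"]))
    except KeyError as exc:
        raise PlanValidationError(f"{where}: missing field {exc.args[0]!r}") from exc
    except PlanValidationError as exc:
        raise PlanValidationError(f"{where}: {exc}") from exc


def plan_from_dict(data: dict) -> TreatmentPlan:
    """Build a validated :class:`TreatmentPlan` from the JSON object form."""
    if not isinstance(data, dict):
        raise PlanValidationError("plan: top level must be a JSON object")
    for key in ("plan_id", "prescription_dose_per_fraction", "groups"):
        if key not in data:
            raise PlanValidationError(f"plan: missing field {key!r}")
    groups = []
    for gi, g in enumerate(data["groups"]):
        where_g = f"groups[{gi}]"
        if "gantry_angle" not in g or "beams" not in g:
            raise PlanValidationError(f"{where_g}: needs 'gantry_angle' and 'beams'")
        beams = []
        for bi, b in enumerate(g["beams"]):
            where_b = f"{where_g}.beams[{bi}]"
            for key in ("head", "gantry_angle", "segments"):
                if key not in b:
                    raise PlanValidationError(f"{where_b}: missing field {key!r}")
            segments = tuple(
                _segment_from_dict(s, f"{where_b}.segments[{si}]")
                for si, s in enumerate(b["segments"])
            )
            try:
                beams.append(
                    Beam(
                        head=int(b["head"]),
                        gantry_angle=float(b["gantry_angle"]),
                        segments=segments,
                    )
                )
            except PlanValidationError as exc:
                raise PlanValidationError(f"{where_b}: {exc}") from exc
        try:
            groups.append(
                BeamGroup(gantry_angle=float(g["gantry_angle"]), beams=tuple(beams))
            )
        except PlanValidationError as exc:
            raise PlanValidationError(f"{where_g}: {exc}") from exc
    return TreatmentPlan(
        plan_id=str(data["plan_id"]),
        prescription_dose_per_fraction=float(data["prescription_dose_per_fraction"]),
        groups=tuple(groups),
    )


def plan_to_dict(plan: TreatmentPlan) -> dict:
    return {
        "plan_id": plan.plan_id,
        "prescription_dose_per_fraction": plan.prescription_dose_per_fraction,
        "groups": [
            {
                "gantry_angle": g.gantry_angle,
                "beams": [
                    {
                        "head": b.head,
                        "gantry_angle": b.gantry_angle,
                        "segments": [
                            {
                                "beam_on_time_min": s.beam_on_time_min,
                                "mlc": {
                                    "left": list(s.aperture.left),
                                    "right": list(s.aperture.right),
                                },
                            }
                            for s in b.segments
                        ],
                    }
                    for b in g.beams
                ],
            }
            for g in plan.groups
        ],
    }


def read_plan(path: str | Path) -> TreatmentPlan:
    """Read and validate a plan from its documented JSON form."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise PlanValidationError(f"{path}: not valid JSON: {exc}") from exc
    return plan_from_dict(data)


def write_plan(plan: TreatmentPlan, path: str | Path) -> None:
    """Write a plan as JSON at full numeric precision (repr round-trip)."""
    with open(path, "w") as fh:
        json.dump(plan_to_dict(plan), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Delivery-record CSV
# ---------------------------------------------------------------------------


def read_delivery_records(
    path: str | Path, init_path: str | Path | None = None
) -> DeliveryRecord:
    """Read rotation records (and optionally initialization times) from CSV.

    ``path`` must have the header ``angle_diff_deg,rotation_time_s``;
    ``init_path``, if given, the header ``initialization_time_s``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["angle_diff_deg", "rotation_time_s"]
    if list(df.columns) != expected:
        raise PlanValidationError(
            f"{path}: expected header {','.join(expected)}, got {','.join(df.columns)}"
        )
    if len(df) == 0:
        raise PlanValidationError(f"{path}: no records")
    inits: tuple[float, ...] = ()
    if init_path is not None:
        idf = pd.read_csv(init_path, float_precision="round_trip")
        if list(idf.columns) != ["initialization_time_s"]:
            raise PlanValidationError(
                f"{init_path}: expected header initialization_time_s"
            )
        inits = tuple(idf["initialization_time_s"].astype(float))
    return DeliveryRecord(
        angle_diff_deg=tuple(df["angle_diff_deg"].astype(float)),
        rotation_time_s=tuple(df["rotation_time_s"].astype(float)),
        initialization_time_s=inits,
    )


def write_delivery_records(
    records: DeliveryRecord,
    path: str | Path,
    init_path: str | Path | None = None,
) -> None:
    # repr() is the shortest lossless rendering of a double, so files
    # round-trip bit-exactly through read_delivery_records
    with open(path, "w") as fh:
        fh.write("angle_diff_deg,rotation_time_s\n")
        for a, t in zip(records.angle_diff_deg, records.rotation_time_s):
            fh.write(f"{a!r},{t!r}\n")
    if init_path is not None:
        with open(init_path, "w") as fh:
            fh.write("initialization_time_s\n")
            for t in records.initialization_time_s:
                fh.write(f"{t!r}\n")


# ---------------------------------------------------------------------------
# Calibration and timing-parameter files
# ---------------------------------------------------------------------------


def read_calibration(path: str | Path) -> SourceCalibration:
    """Read a calibration from YAML (JSON, being a YAML subset, also works)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "heads" not in data or "reference_date" not in data:
        raise PlanValidationError(
            f"{path}: calibration needs 'reference_date' and 'heads'"
        )
    ref = data["reference_date"]
    if isinstance(ref, dt.datetime):
        ref_date: dt.date = ref
    elif isinstance(ref, dt.date):
        ref_date = ref
    else:
        try:
            ref_date = dt.date.fromisoformat(str(ref))
        except ValueError as exc:
            raise PlanValidationError(
                f"{path}: reference_date must be an ISO date, got {ref!r}"
            ) from exc
    return SourceCalibration(
        reference_dose_rate={int(k): float(v) for k, v in data["heads"].items()},
        reference_date=ref_date,
        half_life_days=float(data.get("half_life_days", DEFAULT_HALF_LIFE_DAYS)),
        nominal_dose_rate=float(data.get("nominal_dose_rate", NOMINAL_DOSE_RATE)),
    )


def write_calibration(calibration: SourceCalibration, path: str | Path) -> None:
    data = {
        "reference_date": calibration.reference_date.isoformat(),
        "half_life_days": calibration.half_life_days,
        "nominal_dose_rate": calibration.nominal_dose_rate,
        "heads": {int(k): float(v) for k, v in calibration.reference_dose_rate.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_params(path: str | Path) -> TimingParams:
    """Read a TimingParams patch (JSON object overriding any defaults)."""
    with open(path) as fh:
        data = json.load(fh)
    known = {
        "t_initial",
        "beta0",
        "beta1",
        "mlc_overall_delay",
        "interleaf_delay",
        "leaf_speed",
    }
    unknown = set(data) - known
    if unknown:
        raise PlanValidationError(
            f"{path}: unknown timing parameter(s) {sorted(unknown)}"
        )
    return replace(TimingParams(), **{k: float(v) for k, v in data.items()})


def write_params(params: TimingParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "t_initial": params.t_initial,
                "beta0": params.beta0,
                "beta1": params.beta1,
                "mlc_overall_delay": params.mlc_overall_delay,
                "interleaf_delay": params.interleaf_delay,
                "leaf_speed": params.leaf_speed,
            },
            fh,
            indent=1,
        )
        fh.write("\n")
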