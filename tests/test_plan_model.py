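"""Plan/record/calibration data model: validation and serialization."""

import datetime as dt

import pytest

from cobaltime import (
    Beam,
    BeamGroup,
    DeliveryRecord,
    DomainError,
    MLCAperture,
    PlanValidationError,
    Segment,
    SourceCalibration,
    TreatmentPlan,
    generate_delivery_records,
    generate_plan,
    read_calibration,
    read_delivery_records,
    read_params,
    read_plan,
    write_calibration,
    write_delivery_records,
    write_params,
    write_plan,
)
from cobaltime.plan_model import TimingParams

from conftest import make_aperture, make_beam, single_beam_plan


class TestAperture:
    def test_requires_exactly_30_pairs(self):
        with pytest.raises(PlanValidationError, match="30 leaf positions"):
            MLCAperture(left=(0.0,) * 29, right=(0.0,) * 29)

    def test_rejects_crossed_pair_naming_index(self):
        left = [0.0] * 30
        right = [0.0] * 30
        left[4] = 1.0
        right[4] = -1.0
        with pytest.raises(PlanValidationError, match="pair 5"):
            MLCAperture(left=tuple(left), right=tuple(right))

    def test_closed_pair_mask_uses_gap_tolerance(self):
        ap = make_aperture({0: (-2.0, 2.0), 1: (0.0, 0.04)})
        closed = ap.closed_pairs()
        assert not closed[0]
        assert closed[1]  # 0.04 cm gap is within the 0.05 cm tolerance
        assert closed[2:].all()


class TestBeamAndGroups:
    def test_minimal_plan_has_one_group(self):
        plan = single_beam_plan(make_beam([make_aperture({0: (-1, 1)})]))
        assert plan.n_groups == 1

    @pytest.mark.parametrize(
        "head,angle", [(1, 200.0), (2, 30.0), (3, 100.0), (1, 20.0)]
    )
    def test_beam_outside_head_arc_is_rejected(self, head, angle):
        with pytest.raises(DomainError, match="outside head"):
            make_beam([make_aperture({0: (-1, 1)})], head=head, angle=angle)

    @pytest.mark.parametrize("head,angle", [(1, 30.0), (1, 150.0), (3, 359.0), (3, 15.0)])
    def test_arc_boundaries_and_wraparound_are_reachable(self, head, angle):
        assert make_beam([make_aperture({0: (-1, 1)})], head=head, angle=angle)

    def test_group_rejects_beams_not_120_apart(self):
        b1 = make_beam([make_aperture({0: (-1, 1)})], head=1, angle=90.0)
        b2 = make_beam([make_aperture({0: (-1, 1)})], head=2, angle=200.0)
        with pytest.raises(PlanValidationError):
            BeamGroup(gantry_angle=90.0, beams=(b1, b2))

    def test_group_rejects_duplicate_heads(self):
        b = make_beam([make_aperture({0: (-1, 1)})], head=1, angle=90.0)
        with pytest.raises(PlanValidationError, match="repeats a head"):
            BeamGroup(gantry_angle=90.0, beams=(b, b))

    def test_plan_rejects_duplicate_group_angles(self):
        g = BeamGroup(
            gantry_angle=90.0,
            beams=(make_beam([make_aperture({0: (-1, 1)})], angle=90.0),),
        )
        with pytest.raises(PlanValidationError, match="distinct"):
            TreatmentPlan(plan_id="p", prescription_dose_per_fraction=2.0, groups=(g, g))

    def test_zero_beam_on_time_is_rejected(self):
        with pytest.raises(PlanValidationError, match="beam_on_time_min"):
            Segment(aperture=make_aperture(), beam_on_time_min=0.0)


class TestPlanJson:
    def test_round_trip_identity(self, tmp_path):
        plan = generate_plan(seed=7, n_groups=2, heads_per_group_range=(3, 3))
        path = tmp_path / "plan.json"
        write_plan(plan, path)
        assert read_plan(path) == plan

    def test_closed_pairs_survive_round_trip_with_zero_gap(self, tmp_path):
        plan = single_beam_plan(
            make_beam([make_aperture({0: (-2.0, 2.0)}, parked_at=3.3)])
        )
        path = tmp_path / "plan.json"
        write_plan(plan, path)
        back = read_plan(path)
        ap = back.groups[0].beams[0].segments[0].aperture
        assert ap.left[5] == ap.right[5] == 3.3

    def test_three_head_group_round_trips_in_head_order(self, tmp_path):
        plan = generate_plan(seed=3, n_groups=1, heads_per_group_range=(3, 3))
        path = tmp_path / "plan.json"
        write_plan(plan, path)
        back = read_plan(path)
        assert [b.head for b in back.groups[0].beams] == [1, 2, 3]
        assert back == plan

    def test_schema_violation_names_field_and_index(self, tmp_path):
        plan = generate_plan(seed=1, n_groups=1)
        import json

        from cobaltime.plan_model import plan_to_dict

        data = plan_to_dict(plan)
        del data["groups"][0]["beams"][0]["segments"][0]["beam_on_time_min"]
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(data))
        with pytest.raises(PlanValidationError, match=r"groups\[0\].beams\[0\].segments\[0\]"):
            read_plan(path)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_generated_plans_validate_and_round_trip(self, seed, tmp_path):
        plan = generate_plan(seed=seed, n_groups=1 + seed % 3)
        path = tmp_path / "p.json"
        write_plan(plan, path)
        assert read_plan(path) == plan


class TestDeliveryRecordsCsv:
    def test_two_row_csv_parses(self, tmp_path):
        path = tmp_path / "rec.csv"
        path.write_text("angle_diff_deg,rotation_time_s\n120,32.4\n60,18.0\n")
        rec = read_delivery_records(path)
        assert rec.n_rows == 2
        assert rec.angle_diff_deg == (120.0, 60.0)

    def test_empty_data_section_errors(self, tmp_path):
        path = tmp_path / "rec.csv"
        path.write_text("angle_diff_deg,rotation_time_s\n")
        with pytest.raises(PlanValidationError, match="no records"):
            read_delivery_records(path)

    def test_invalid_rows_are_rejected(self):
        with pytest.raises(PlanValidationError, match=r"angle_diff_deg\[0\]"):
            DeliveryRecord(angle_diff_deg=(360.0,), rotation_time_s=(10.0,))
        with pytest.raises(PlanValidationError, match=r"rotation_time_s\[1\]"):
            DeliveryRecord(angle_diff_deg=(10.0, 20.0), rotation_time_s=(1.0, -1.0))

    def test_generator_output_round_trips(self, tmp_path):
        rec = generate_delivery_records(seed=5, n=40)
        path = tmp_path / "rec.csv"
        init = tmp_path / "init.csv"
        write_delivery_records(rec, path, init)
        assert read_delivery_records(path, init) == rec


class TestCalibrationAndParams:
    def test_calibration_round_trip(self, tmp_path, calibration):
        path = tmp_path / "cal.yaml"
        write_calibration(calibration, path)
        assert read_calibration(path) == calibration

    def test_calibration_requires_all_three_heads(self):
        with pytest.raises(PlanValidationError, match="heads 1, 2, 3"):
            SourceCalibration(
                reference_dose_rate={1: 1.5}, reference_date=dt.date(2026, 1, 1)
            )

    def test_params_round_trip_and_unknown_key(self, tmp_path):
        p = TimingParams(beta0=4.0)
        path = tmp_path / "params.json"
        write_params(p, path)
        assert read_params(path) == p
        path.write_text('{"velocity": 3}')
        with pytest.raises(PlanValidationError, match="unknown timing parameter"):
            read_params(path)

    def test_nonpositive_timing_parameter_rejected(self):
        with pytest.raises(PlanValidationError, match="leaf_speed"):
            TimingParams(leaf_speed=0.0)
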