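"""MLC sequencing, transition-time arithmetic, and the closed-pair audit."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cobaltime import (
    TimingParams,
    beam_mlc_time,
    closed_pair_savings,
    freeze_closed_pairs,
    freezable_pairs,
    generate_plan,
    plan_leaf_commands,
    transition_time,
)

from conftest import make_aperture, make_beam, single_beam_plan


def naive_command_order(start, end):
    """Independent straightforward re-statement of the sequencing rules:
    collect movers per bank, count leaves moving away from the opposing
    bank, start with the away-heavier bank (ties: left), pair order within
    a bank, ranks 1..m."""
    left = []
    right = []
    for i in range(30):
        if end.left[i] != start.left[i]:
            left.append(("left", i + 1, abs(end.left[i] - start.left[i]),
                         end.left[i] < start.left[i]))
        if end.right[i] != start.right[i]:
            right.append(("right", i + 1, abs(end.right[i] - start.right[i]),
                          end.right[i] > start.right[i]))
    away_l = sum(1 for m in left if m[3])
    away_r = sum(1 for m in right if m[3])
    seq = left + right if away_l >= away_r else right + left
    return [(bank, pair, dist, rank) for rank, (bank, pair, dist, _) in enumerate(seq, 1)]


class TestCommandPlanning:
    def test_identical_apertures_produce_no_commands(self):
        ap = make_aperture({0: (-3, 3), 1: (-1, 2)})
        assert plan_leaf_commands(ap, ap) == []

    def test_single_moving_leaf_gets_rank_one(self):
        a = make_aperture({0: (-1.0, 2.0)})
        b = make_aperture({0: (-3.1, 2.0)})
        (mv,) = plan_leaf_commands(a, b)
        assert (mv.pair_index, mv.bank, mv.command_rank) == (1, "left", 1)
        assert mv.distance == pytest.approx(2.1)

    def test_ordering_matches_brute_force_rule_oracle(self):
        # every per-pair motion pattern over 4 pairs: left leaf in/out/still
        # crossed with a fixed mix of right-leaf motions
        deltas = [(-1.0, 0.0), (0.0, 0.0), (0.8, 0.0)]
        right_mix = [0.0, 0.7, -0.5, 1.2]
        for combo in itertools.product(range(3), repeat=4):
            start = make_aperture({i: (-3.0, 3.0) for i in range(4)})
            open_pairs = {}
            for i, choice in enumerate(combo):
                dl, _ = deltas[choice]
                open_pairs[i] = (-3.0 + dl, 3.0 + right_mix[i])
            end = make_aperture(open_pairs)
            got = [
                (m.bank, m.pair_index, m.distance, m.command_rank)
                for m in plan_leaf_commands(start, end)
            ]
            assert got == naive_command_order(start, end)

    def test_leading_bank_is_the_away_heavier_one(self):
        start = make_aperture({0: (-2, 2), 1: (-2, 2), 2: (-2, 2)})
        # two right leaves open away, one left leaf closes toward
        end = make_aperture({0: (-2, 4), 1: (-2, 3.5), 2: (-1, 2)})
        moves = plan_leaf_commands(start, end)
        assert [m.bank for m in moves] == ["right", "right", "left"]


class TestTransitionTime:
    def test_no_motion_costs_the_overall_delay(self, params):
        ap = make_aperture({0: (-2, 2)})
        assert transition_time(ap, ap, params) == 2.2

    def test_single_leaf_hand_arithmetic(self, params):
        a = make_aperture({0: (-1.0, 2.0)})
        b = make_aperture({0: (-3.1, 2.0)})
        assert transition_time(a, b, params) == pytest.approx(
            2.2 + 0.034 + 2.1 / 2.1, rel=1e-12
        )

    def test_ten_equal_leaves_last_rank_dominates(self, params):
        start = make_aperture({i: (-1.0, 2.0) for i in range(10)})
        end = make_aperture({i: (-3.1, 2.0) for i in range(10)})
        assert transition_time(start, end, params) == pytest.approx(
            2.2 + 10 * 0.034 + 1.0, rel=1e-12
        )

    def test_monotone_in_distance(self, params):
        a = make_aperture({0: (-1.0, 2.0)})
        times = [
            transition_time(a, make_aperture({0: (-1.0 - d, 2.0)}), params)
            for d in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(t2 > t1 for t1, t2 in zip(times, times[1:]))

    def test_adding_a_mover_never_decreases_time(self, params):
        start = make_aperture({i: (-1.0, 2.0) for i in range(5)})
        prev = None
        for n_moving in range(1, 6):
            end = make_aperture(
                {i: ((-2.5, 2.0) if i < n_moving else (-1.0, 2.0)) for i in range(5)}
            )
            t = transition_time(start, end, params)
            assert prev is None or t >= prev
            prev = t

    @given(
        dists=st.lists(
            st.floats(min_value=0.0, max_value=8.0, allow_nan=False), min_size=1, max_size=30
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_equals_max_over_per_leaf_finish_times(self, dists):
        params = TimingParams()
        start = make_aperture({i: (-1.0, 2.0) for i in range(len(dists))})
        end = make_aperture(
            {i: (-1.0 - d, 2.0) for i, d in enumerate(dists)}
        )
        moves = plan_leaf_commands(start, end)
        expected = (
            max(
                params.mlc_overall_delay
                + m.command_rank * params.interleaf_delay
                + m.distance / params.leaf_speed
                for m in moves
            )
            if moves
            else params.mlc_overall_delay
        )
        assert transition_time(start, end, params) == expected
        assert transition_time(start, end, params) >= params.mlc_overall_delay


class TestBeamMlcTime:
    def test_single_segment_beam_has_no_mlc_time(self, params):
        beam = make_beam([make_aperture({0: (-2, 2)})])
        assert beam_mlc_time(beam, params) == 0.0

    def test_three_segments_with_identical_transitions_add_up(self, params):
        a = make_aperture({0: (-1, 2)})
        b = make_aperture({0: (-3, 2)})
        beam = make_beam([a, b, a])
        t_ab = transition_time(a, b, params)
        assert beam_mlc_time(beam, params) == pytest.approx(2 * t_ab, rel=1e-15)

    def test_first_segment_motion_is_not_billed(self, params):
        # a one-segment beam costs nothing regardless of its aperture
        wild = make_aperture({i: (-9.0, 9.0) for i in range(30)})
        assert beam_mlc_time(make_beam([wild]), params) == 0.0


class TestClosedPairAudit:
    def test_no_closed_pair_motion_means_no_savings(self, params):
        a = make_aperture({0: (-1, 2)})
        b = make_aperture({0: (-3, 2)})
        plan = single_beam_plan(make_beam([a, b]))
        (row,) = closed_pair_savings(plan, params)
        assert row.saved_s == 0.0 and row.saved_fraction == 0.0

    def test_only_closed_pairs_moving_frees_the_whole_leaf_excess(self, params):
        # aperture pair 0 static, parked junction shuttles each segment
        a = make_aperture({0: (-2, 2)}, parked_at=0.0)
        b = make_aperture({0: (-2, 2)}, parked_at=-3.0)
        plan = single_beam_plan(make_beam([a, b, a]))
        (row,) = closed_pair_savings(plan, params)
        assert row.frozen_s == pytest.approx(2 * params.mlc_overall_delay, rel=1e-15)
        assert row.saved_s > 0

    def test_freezable_pairs_are_those_closed_in_every_segment(self):
        a = make_aperture({0: (-2, 2), 1: (-1, 1)})
        b = make_aperture({0: (-2, 2)})  # pair 2 closes in segment 2
        beam = make_beam([a, b])
        assert 2 not in freezable_pairs(beam)
        assert 1 not in freezable_pairs(beam)
        assert set(freezable_pairs(beam)) == set(range(3, 31))

    @pytest.mark.parametrize("seed", range(6))
    def test_synthetic_plans_save_a_strict_fraction_per_group(self, seed, params):
        plan = generate_plan(seed=seed, aperture_complexity=0.7)
        for row in closed_pair_savings(plan, params):
            assert row.frozen_s <= row.original_s
            assert 0.0 < row.saved_fraction < 1.0

    def test_frozen_beam_never_moves_its_parked_junctions(self, params):
        plan = generate_plan(seed=9, aperture_complexity=0.9)
        beam = plan.groups[0].beams[0]
        frozen = freeze_closed_pairs(beam)
        for idx in freezable_pairs(beam):
            positions = {s.aperture.left[idx - 1] for s in frozen.segments}
            assert len(positions) == 1
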