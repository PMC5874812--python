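"""MLC transition-time model and the closed-pair savings audit.

Between step-and-shoot segments the beam is off while the leaves reshape
the aperture.  The MLC controller can command only one leaf at a time, so
leaves start sequentially: the controller first starts, one by one in pair
order, every moving leaf of the bank whose leaves are predominantly moving
*away* from the opposing bank, then the moving leaves of the other bank.
Leaves that do not change position are skipped entirely.  With command
rank ``i`` (1-based over the compacted sequence of moving leaves), a
leaf's finish time after beam-off is

    T_i = T_overall_delay + i * T_interleaf_delay + d_i / v_leaf

and the transition time is the maximum of ``T_i`` over moving leaves
(the fixed overall delay alone when nothing moves — the source still has
to transit off and back on).  A beam's MLC time sums the N_s - 1
transitions between its N_s segments; motion into the first segment
happens during gantry rotation and is not billed here.

The closed-pair audit quantifies how much transition time is spent
shuttling *closed* leaf pairs (junctions parked by the planning system and
deliberately relocated between segments to spread leakage dose): it
recomputes every transition with the always-closed pairs frozen at their
first-segment positions and reports the per-group saving.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import PlanValidationError
from .plan_model import (
    CLOSED_GAP_TOL,
    N_LEAF_PAIRS,
    Beam,
    MLCAperture,
    Segment,
    TimingParams,
    TreatmentPlan,
)

__all__ = [
    "LeafMove",
    "GroupSavings",
    "plan_leaf_commands",
    "transition_time",
    "beam_mlc_time",
    "freezable_pairs",
    "freeze_closed_pairs",
    "closed_pair_savings",
]


@dataclass(frozen=True)
class LeafMove:
    """One leaf's share of a segment transition.

    ``pair_index`` is 1-based; ``command_rank`` is the leaf's 1-based
    position in the compacted command sequence (non-moving leaves are
    skipped and consume no rank).
    """

    pair_index: int
    bank: str  # "left" or "right"
    distance: float  # cm, > 0
    command_rank: int


def _bank_motions(
    start: MLCAperture, end: MLCAperture, bank: str
) -> tuple[list[tuple[int, float]], int]:
    """Moving leaves of one bank as (pair_index, signed delta) plus the
    count moving away from the opposing bank."""
    a = start.left if bank == "left" else start.right
    b = end.left if bank == "left" else end.right
    moves = [
        (i + 1, b[i] - a[i]) for i in range(N_LEAF_PAIRS) if b[i] != a[i]
    ]
    if bank == "left":
        # a left leaf retreats (away from the right bank) by moving to -x
        n_away = sum(1 for _, d in moves if d < 0)
    else:
        n_away = sum(1 for _, d in moves if d > 0)
    return moves, n_away


def plan_leaf_commands(start: MLCAperture, end: MLCAperture) -> list[LeafMove]:
    """Ordered leaf commands for the transition ``start`` -> ``end``.

    All moving leaves of the leading bank (the one with more away-moving
    leaves; ties go to the left bank) are commanded first in pair-index
    order, then the trailing bank's, with ranks 1..m over the m movers.
    """
    left_moves, left_away = _bank_motions(start, end, "left")
    right_moves, right_away = _bank_motions(start, end, "right")
    if left_away >= right_away:
        ordered = [("left", m) for m in left_moves] + [("right", m) for m in right_moves]
    else:
        ordered = [("right", m) for m in right_moves] + [("left", m) for m in left_moves]
    return [
        LeafMove(pair_index=pair, bank=bank, distance=abs(delta), command_rank=rank)
        for rank, (bank, (pair, delta)) in enumerate(ordered, start=1)
    ]


def transition_time(
    start: MLCAperture, end: MLCAperture, params: TimingParams
) -> float:
    """Seconds from beam-off to the next beam-on for one segment change."""
    moves = plan_leaf_commands(start, end)
    if not moves:
        return params.mlc_overall_delay
    return max(
        params.mlc_overall_delay
        + m.command_rank * params.interleaf_delay
        + m.distance / params.leaf_speed
        for m in moves
    )


def beam_mlc_time(beam: Beam, params: TimingParams) -> float:
    """Total inter-segment MLC time (s) for one beam: the sum over its
    N_s - 1 transitions, 0 for a single-segment beam."""
    return sum(
        transition_time(a.aperture, b.aperture, params)
        for a, b in zip(beam.segments, beam.segments[1:])
    )


def freezable_pairs(beam: Beam, gap_tol: float = CLOSED_GAP_TOL) -> list[int]:
    """1-based indices of pairs that are closed in *every* segment of the
    beam — they never shape the aperture and could stay parked."""
    closed = beam.segments[0].aperture.closed_pairs(gap_tol)
    for seg in beam.segments[1:]:
        closed = closed & seg.aperture.closed_pairs(gap_tol)
    return [i + 1 for i in range(N_LEAF_PAIRS) if closed[i]]


def freeze_closed_pairs(beam: Beam, gap_tol: float = CLOSED_GAP_TOL) -> Beam:
    """Variant of ``beam`` with its always-closed pairs pinned at their
    first-segment positions throughout."""
    frozen = set(i - 1 for i in freezable_pairs(beam, gap_tol))
    if not frozen:
        return beam
    first = beam.segments[0].aperture
    new_segments = []
    for seg in beam.segments:
        left = tuple(
            first.left[i] if i in frozen else seg.aperture.left[i]
            for i in range(N_LEAF_PAIRS)
        )
        right = tuple(
            first.right[i] if i in frozen else seg.aperture.right[i]
            for i in range(N_LEAF_PAIRS)
        )
        new_segments.append(
            replace(seg, aperture=MLCAperture(left=left, right=right))
        )
    return replace(beam, segments=tuple(new_segments))


@dataclass(frozen=True)
class GroupSavings:
    """Closed-pair audit result for one beam group."""

    group_angle: float
    original_s: float
    frozen_s: float

    @property
    def saved_s(self) -> float:
        return self.original_s - self.frozen_s

    @property
    def saved_fraction(self) -> float:
        return 0.0 if self.original_s == 0.0 else self.saved_s / self.original_s


def closed_pair_savings(
    plan: TreatmentPlan,
    params: TimingParams,
    gap_tol: float = CLOSED_GAP_TOL,
) -> list[GroupSavings]:
    """Per-group MLC time saved by never moving the always-closed pairs.

    For each group, ``original_s`` sums :func:`beam_mlc_time` over its
    beams as planned and ``frozen_s`` repeats the computation with closed
    pairs frozen; freezing can only remove leaf commands, so the saving is
    always >= 0.
    """
    out = []
    for g in plan.groups:
        original = sum(beam_mlc_time(b, params) for b in g.beams)
        frozen = sum(
            beam_mlc_time(freeze_closed_pairs(b, gap_tol), params) for b in g.beams
        )
        out.append(
            GroupSavings(group_angle=g.gantry_angle, original_s=original, frozen_s=frozen)
        )
    return out
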