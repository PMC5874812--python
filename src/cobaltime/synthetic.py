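"""Seeded generators for plans and delivery records.

No clinical data ships with this package; every test and example runs on
synthetic inputs built here.  ``generate_plan`` emulates the structure of
step-and-shoot plans for the three-head geometry: beam groups at distinct
gantry angles with member beams 120 degrees apart, each beam splitting a
composite MLC field into per-segment sub-apertures (a sweeping window over
the open leaf pairs), with parked closed-pair junctions that the planning
system deliberately relocates between segments.  ``aperture_complexity``
in [0, 1] dials how much extra leaf traffic a transition carries: the
fraction of closed pairs being shuttled and of aperture edges jittering
between segments.  At complexity 0 every beam collapses to a single
static segment.

The generator is bit-reproducible per seed, and for a fixed seed the total
MLC motion time is non-decreasing in ``aperture_complexity`` by
construction (participation sets only grow and leaf travel distances only
lengthen as the dial rises).

``generate_delivery_records`` fabricates the log-derived training data for
the gantry regression: angle differences uniform over plausible group
spacings with rotation times on a known line plus truncated Gaussian
noise, plus a sample of initialization times.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import DomainError
from .plan_model import (
    Beam,
    BeamGroup,
    DeliveryRecord,
    MLCAperture,
    N_LEAF_PAIRS,
    Segment,
    TreatmentPlan,
)

__all__ = ["generate_plan", "generate_delivery_records"]

_MAX_BLOCK = 16  # leaf pairs in the open block; leaves 30-16 pairs parked
_LEAF_LIMIT = 10.4  # cm, keep generated positions inside +/- this travel


_MIN_GROUP_SEP = 20.0  # deg between neighboring gantry positions


def _group_angles(rng: np.random.Generator, n_groups: int) -> np.ndarray:
    """Distinct canonical angles in [31, 149] deg, >= 20 deg apart.

    Drawn as sorted uniforms on the slack interval plus the mandatory
    separations, so a single draw always succeeds.
    """
    span = 149.0 - 31.0
    slack = span - (n_groups - 1) * _MIN_GROUP_SEP
    if slack < 0:
        raise DomainError(
            f"cannot place {n_groups} groups {_MIN_GROUP_SEP:g} deg apart "
            f"within a {span:g} deg arc"
        )
    base = np.sort(rng.uniform(0.0, slack, size=n_groups))
    return 31.0 + base + _MIN_GROUP_SEP * np.arange(n_groups)


def _beam(
    rng: np.random.Generator,
    head: int,
    angle: float,
    segments_range: tuple[int, int],
    complexity: float,
    beam_on_total_min: float | None,
) -> Beam:
    s0, s1 = segments_range
    n_s_draw = int(rng.integers(s0, s1 + 1))
    n_s = 1 if complexity == 0.0 else n_s_draw

    k_p = int(rng.integers(max(8, n_s_draw), _MAX_BLOCK + 1))
    a0 = int(rng.integers(0, N_LEAF_PAIRS - k_p + 1))
    block = list(range(a0, a0 + k_p))

    # per block pair: aperture extents and edge-jitter lottery
    u = rng.uniform(1.0, 5.0, size=k_p)  # left extent (leaf at -u)
    v = rng.uniform(1.0, 5.0, size=k_p)  # right extent
    p_breath = rng.uniform(size=k_p)
    extra = rng.uniform(0.3, 2.0, size=k_p)

    # per parked pair: junction position and relocation lottery
    parked = [i for i in range(N_LEAF_PAIRS) if i not in block]
    junction = rng.uniform(-6.0, 6.0, size=len(parked))
    p_drift = rng.uniform(size=len(parked))
    step_draw = rng.uniform(0.3, 1.5, size=len(parked))

    beam_on = np.exp(rng.uniform(math.log(0.05), math.log(2.0), size=n_s_draw))
    if beam_on_total_min is not None:
        # equal-dose mode: keep the relative split, pin the beam's total
        beam_on = beam_on * (beam_on_total_min / beam_on[:n_s].sum())

    breathing = p_breath < complexity
    drifting = p_drift < complexity
    if complexity > 0.0:
        # guarantee at least one jittering edge and one shuttled junction
        breathing[0] = True
        if len(parked):
            drifting[0] = True
    # cap the drift step so the junction stays on the travel range
    steps = np.minimum(
        step_draw, (junction + _LEAF_LIMIT) / max(1, n_s - 1)
    )

    windows = np.array_split(np.asarray(block), n_s)
    segments = []
    for s in range(n_s):
        left = np.zeros(N_LEAF_PAIRS)
        right = np.zeros(N_LEAF_PAIRS)
        in_window = set(int(q) for q in windows[s])
        for qi, q in enumerate(block):
            if q in in_window:
                jitter = extra[qi] if (breathing[qi] and s % 2 == 1) else 0.0
                left[q] = -u[qi] - jitter
                right[q] = v[qi]
            else:
                mid = (v[qi] - u[qi]) / 2.0
                left[q] = right[q] = mid
        for pi, p in enumerate(parked):
            pos = junction[pi] - steps[pi] * s if drifting[pi] else junction[pi]
            left[p] = right[p] = pos
        segments.append(
            Segment(
                aperture=MLCAperture(left=tuple(left), right=tuple(right)),
                beam_on_time_min=float(beam_on[s]),
            )
        )
    return Beam(head=head, gantry_angle=angle, segments=tuple(segments))


def generate_plan(
    seed: int,
    n_groups: int = 3,
    segments_range: tuple[int, int] = (2, 6),
    heads_per_group_range: tuple[int, int] = (1, 3),
    aperture_complexity: float = 0.5,
    prescription_dose_per_fraction: float = 2.0,
    beam_on_total_min: float | None = None,
    plan_id: str | None = None,
) -> TreatmentPlan:
    """Generate a reproducible valid plan.

    ``segments_range`` and ``heads_per_group_range`` are inclusive
    ``(lo, hi)`` bounds; ``aperture_complexity`` in [0, 1] dials leaf
    traffic per transition (0 collapses every beam to one segment).
    Per-segment beam-on times are log-uniform on [0.05, 2] minutes at the
    nominal dose rate; passing ``beam_on_total_min`` instead rescales each
    beam's segment times to that fixed total (equal-dose mode, for plan
    families that vary modulation at constant prescription).
    """
    s0, s1 = segments_range
    h0, h1 = heads_per_group_range
    if not (1 <= s0 <= s1 <= _MAX_BLOCK):
        raise DomainError(f"segments_range must satisfy 1 <= lo <= hi <= {_MAX_BLOCK}")
    if not (1 <= h0 <= h1 <= 3):
        raise DomainError("heads_per_group_range must satisfy 1 <= lo <= hi <= 3")
    if not 0.0 <= aperture_complexity <= 1.0:
        raise DomainError(
            f"aperture_complexity must lie in [0, 1], got {aperture_complexity}"
        )
    if n_groups < 1:
        raise DomainError(f"n_groups must be >= 1, got {n_groups}")

    rng = np.random.default_rng(seed)
    canonical = _group_angles(rng, n_groups)
    groups = []
    for ang in canonical:
        n_heads = int(rng.integers(h0, h1 + 1))
        heads = sorted(int(h) for h in rng.choice([1, 2, 3], size=n_heads, replace=False))
        beams = tuple(
            _beam(
                rng,
                head,
                (float(ang) + 120.0 * (head - 1)) % 360.0,
                segments_range,
                aperture_complexity,
                beam_on_total_min,
            )
            for head in heads
        )
        groups.append(BeamGroup(gantry_angle=float(ang), beams=beams))
    return TreatmentPlan(
        plan_id=plan_id if plan_id is not None else f"synthetic-{seed}",
        prescription_dose_per_fraction=prescription_dose_per_fraction,
        groups=tuple(groups),
    )


def generate_delivery_records(
    seed: int,
    n: int = 200,
    beta0: float = 3.61,
    beta1: float = 0.24,
    noise_sd: float = 1.0,
    init_mean: float = 27.7,
    init_sd: float = 8.0,
    n_init: int = 50,
) -> DeliveryRecord:
    """Synthetic log-derived timing records for fitting TimingParams.

    Rotation times follow ``beta0 + beta1 * theta + N(0, noise_sd)``
    truncated positive, with angle differences uniform on [15, 240] deg;
    initialization times are Gaussian truncated positive.
    """
    if n < 2:
        raise DomainError(f"need n >= 2 rotation records, got {n}")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(15.0, 240.0, size=n)
    times = beta0 + beta1 * theta
    if noise_sd > 0:
        times = times + rng.normal(0.0, noise_sd, size=n)
        while np.any(times <= 0):  # truncate by resampling
            bad = times <= 0
            times[bad] = beta0 + beta1 * theta[bad] + rng.normal(
                0.0, noise_sd, size=int(bad.sum())
            )
    inits = np.full(n_init, init_mean, dtype=float)
    if init_sd > 0 and n_init > 0:
        inits = rng.normal(init_mean, init_sd, size=n_init)
        while np.any(inits <= 0):
            bad = inits <= 0
            inits[bad] = rng.normal(init_mean, init_sd, size=int(bad.sum()))
    return DeliveryRecord(
        angle_diff_deg=tuple(float(t) for t in theta),
        rotation_time_s=tuple(float(t) for t in times),
        initialization_time_s=tuple(float(t) for t in inits),
    )
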