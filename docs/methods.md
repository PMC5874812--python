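# Methods

This note records the delivery model implemented by `cobaltime`, the
choices made where the design was genuinely open, what the synthetic data
emulate, and the model's known limitations.

## Machine model and assumptions

The modeled machine has three cobalt-60 heads mounted 120° apart on a
ring gantry, each reaching a limited arc: head 1 covers 30°–150°, head 2
150°–270°, head 3 270°–30° (wrapping through 0°). A plan is a sequence of
*beam groups* — gantry positions carrying one beam per participating
head — and each beam is a list of step-and-shoot segments (a 30-pair MLC
aperture plus a beam-on time planned at the nominal 1.85 Gy/min rate).
Angles are degrees in [0, 360); leaf positions are cm at isocenter with
left ≤ right per pair; times are seconds internally, with beam-on times
carried in minutes as planned and reports rendered in minutes to 4
decimals.

The total delivery time decomposes into four strictly additive
components: initialization, decay-corrected beam-on, gantry rotation, and
MLC motion. Heads of one group fire simultaneously and independently, so
each group contributes only its *dominant* beam — the one maximizing
beam-on plus MLC time (ties resolve to the lowest head index, an
arbitrary but fixed rule). The model assumes no overlap between a group's
trailing MLC motion and the following rotation; rotation and beam time
are strictly additive.

### Initialization

The overhead before the first beam depends on where the previous
treatment left the gantry, which is unknowable at planning time, so it is
a constant: the mean of logged initialization times when a delivery
record is available, else the default 27.7 s. The machine's actual
direction choice (sweep direction nearest the previous final angle) is
deliberately folded into this constant rather than modeled.

### Source decay and beam-on

`DR(j) = DR_ref(j) · (1/2)^(n_days/HL)` per head, with `HL` defaulting to
5.25 × 365.25 days. `n_days` is the exact (fractional, if timestamps
carry time of day) calendar-day difference; whether a year is 365 or
365.25 days is a configuration choice exposed through `half_life_days`.
Treatment dates before the calibration date are rejected rather than
extrapolated to a stronger source. Beam-on scales as
`T_planned · DR_nominal / DR(j)`, applied uniformly to all segments of a
beam; the dose-rate × time product is conserved by construction.

### Gantry rotation

Groups are delivered in one monotone angular sweep. Because reversing the
sweep leaves the consecutive angle differences unchanged, ascending order
is canonical; the final-to-first wrap gap is never traversed. Each of the
N_g − 1 rotations costs `β0 + β1·θ_diff`. The line is fitted by ordinary
least squares (scipy's closed-form `linregress`, which also supplies
standard errors and R²); a design with all angle differences equal is
rejected as degenerate.

### MLC transitions

The MLC controller issues one command per leaf. Sequencing rules as
implemented: leaves that do not change position are skipped entirely; the
bank with more leaves moving *away* from the opposing bank (left leaf
moving to −x, right leaf to +x) is commanded first, all of its movers in
pair-index order, then the other bank's movers; ties on the away count go
to the left bank (arbitrary, fixed). Command ranks run 1..m over the
compacted list of m movers — the first mover already pays one interleaf
quantum. The second bank starts after the first bank's *commands* are
issued, not after its arrivals, so ranks simply continue across banks. A
leaf's finish time is `overall_delay + rank · interleaf_delay +
distance/leaf_speed`; the transition costs the maximum over movers. A
transition with no moving leaves still costs the overall delay (the
source must transit off and on), which also resolves the otherwise
undefined empty maximum. Pair-internal direction conflicts (one leaf
opening, the other closing) are treated independently per bank; collision
legality is the planner's concern. A beam's MLC time sums its N_s − 1
transitions: motion into the first segment happens during the preceding
rotation (or initialization) and is not billed.

Default leaf speed is 2.1 cm/s. An alternative estimate of 2.2 cm/s
exists for this machine class; the two are not averaged, and the value is
configurable through `TimingParams`.

### Closed-pair audit

A pair is *closed* when its gap is ≤ 0.05 cm — a small positive tolerance
absorbing rounding in exported plans. The audit freezes, per beam, the
pairs that are closed in **every** segment (pairs that are closed only
sometimes shape the aperture and must move), pinning them at their
first-segment positions, and recomputes each group's MLC time; it reports
original, frozen, and saved fraction per group, summed over the group's
beams. Freezing removes commands, so savings are non-negative in all
realistic geometries. One caveat is documented rather than patched: under
the literal bank-precedence rule, removing away-movers can flip which
bank leads and raise a remaining leaf's rank by a few 0.034 s quanta, so
a frozen transition is not *provably* never longer. The synthetic
generator's geometry keeps the left bank leading before and after
freezing, where the inequality is exact.

## Simulator

The simulator is event-driven with exact float times — no time-stepping —
so its end time equals the closed-form total to floating-point rounding
(observed ≤ 5e-13 s across 1,000 generated plans; the equivalence test
allows 1e-9 s). It emits `init_end`, per-head `beam_on`/`beam_off`,
`leaf_command`/`leaf_arrival` (commands at `rank · interleaf_delay` after
beam-off, arrivals after the travel time; the overall delay closes the
gap before the next beam-on), and gantry `rotation_start`/`rotation_end`.
Ties at equal timestamps order causally: initialization before the first
beam-on, a group's last beam-off before the rotation it triggers, a
rotation's end before the next group's beam-ons. Leaf motion into each
group's first segment is assumed to complete during the rotation; if the
computed travel would outlast the rotation the simulator warns rather
than stretching the rotation, because the real machine's behavior in that
corner is unobserved.

## Complexity metrics

`BM = 1 − Σ_s t_s A_s / (t_b A_union)` with areas computed per leaf pair
as exact unions of intervals (closed pairs contribute nothing), times the
projected leaf width. The leaf width (default 1.05 cm) scales all areas
uniformly but does not cancel in BM for irregular shapes, so it is an
explicit parameter. BM is clamped at 0 against float residue in the
single-segment case. PM is the beam-on-time-weighted mean of BM with
weights normalized to a 2 Gy fraction; within one plan that normalization
rescales all weights equally, so it matters only across plans — the
normalized total time (predicted total × 2 Gy / prescription) uses the
same convention. `complexity_time_relation` reports Spearman rank
correlations of PM with overall duty cycle and normalized time, flagging
zero-variance families as degenerate instead of emitting meaningless
coefficients.

Duty cycles: per beam, beam-on / (beam-on + that beam's MLC time); for
the plan, dominant-beam beam-on over total time — dominant beams are what
occupy wall-clock under simultaneous delivery.

## Synthetic data

The generator emulates the *structure* of clinical step-and-shoot plans,
not any clinic's case mix. Groups sit at distinct canonical angles in
[31°, 149°], at least 20° apart (a plausible clinical spacing that also
keeps first-segment leaf travel inside most rotation windows); member
beams sit at canonical + 120°(head−1), which lands exactly one angle in
each head's arc. Each beam opens a contiguous block of 8–16 leaf pairs
with extents of 1–5 cm per bank and splits it into per-segment windows
(disjoint slices of the block), so a beam with more segments has smaller
per-segment apertures and higher BM — the field-splitting that real
modulation performs. Parked pairs are closed junctions at ±6 cm.

`aperture_complexity` ∈ [0, 1] dials transition traffic: the probability
that a parked junction is shuttled (leftward, one step per segment) and
that an aperture edge jitters between segments; at 0 every beam collapses
to one static segment. The construction is deliberately monotone: raising
the dial only grows the participation sets and lengthens travel, the left
bank always leads, and added movers never lower an existing command rank,
so total MLC time is non-decreasing in the dial at fixed seed. Per-
segment beam-on times are log-uniform on [0.05, 2] min; the equal-dose
mode (`beam_on_total_min`) rescales each beam's segment times to a fixed
total and is the right setting for complexity families, which compare
modulation at constant prescription. Delivery records are drawn as
θ ~ U(15°, 240°) with rotation times on the (3.61, 0.24) line plus
truncated Gaussian noise, and truncated-Gaussian initialization times.

What passing tests on these data do and do not show: they verify the
timing model's internal consistency (closed form ≡ event replay), the
estimators' recovery of known parameters, and the direction of the
modulation/duty-cycle/time trade-off. They do not certify clinical error
magnitudes — those depend on a machine's real log distribution — and the
generator's savings fractions and correlations are properties of its own
geometry, not of any patient population.

## Numerical choices and problem sizes

Exact float comparison (`!=`) decides whether a leaf "moves": positions
come from plan files and generators, where a planned no-move is bit-
identical. OLS is linear algebra at machine precision; regression
recovery is asserted at 1e-9. Predictor-simulator agreement is asserted
at 1e-9 s (observed ~1e-13). CSVs are written with `repr`/shortest-
round-trip floats and read with pandas' round-trip parser so record and
timeline files reproduce bit-exactly. The default test suite and the
acceptance script use 1,000 plans of 1–4 groups and 1–5 segments for the
equivalence sweep, 20 plans for the audit, an 11-plan equal-dose family
(2–12 segments per beam) for the complexity relation, and n = 200–500
synthetic records for the regression — sizes chosen to exercise every
code path with comfortable statistical margins.

## Known limitations

- No gantry acceleration profile, leaf acceleration, or beam ramp
  physics; all delays are the fitted constants.
- The overall MLC delay is modeled as fully serial with leaf motion;
  whether part of it overlaps source transit is not resolvable from
  console observation.
- Whether rotation time can hide trailing MLC motion of the previous
  group is unmodeled (treated as additive).
- Dose is out of scope entirely: no transmission/leakage estimate
  accompanies the closed-pair audit, and no MU/dose calculation exists.
- The plan JSON schema leaves leaf width, field size, and maximum leaf
  travel unconstrained beyond per-pair ordering.
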