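# Methods

## The prioritization model

A candidate technology is described by four variables kept deliberately
separate: benefit score, annual total cost (millions of currency), an
ordinal quality-of-evidence grade (`poor < medium < high`), and free-text
X-factor notes. Only the first two are quantitative axes; evidence and
X-factors are carried as display attributes and, for X-factors, as
lock-in/lock-out constraints on the optimizer. Folding them into a single
index would hide exactly the trade-offs the framework exists to expose, and
their importance is idiosyncratic per technology rather than generic.

**Benefit score.** An additive points system: dimensions with ordered
levels, non-negative non-decreasing point values, bottom level = 0. The
score of a rating is the sum of assigned level values; `max_score` is the
sum of top values. "Not yet known" is treated as the bottom level (the
bundled schedule merges them in its level wording). Level labels are
matched case-insensitively with all whitespace stripped, which absorbs the
minor phrasing drift that hand-edited CSV tables accumulate. Score
comparisons use an absolute tolerance of 1e-9; point values are stored as
plain floats read from text at 3–4 significant digits.

**Cost.** Held per-annum in the bundled data; a `CashFlowSeries` helper
collapses multi-period flows to NPV with end-of-period discounting
(`Σ a_t/(1+r)^t`) for programmes better described that way. The loader does
not convert between conventions; fixtures declare theirs in metadata.
Internally costs are never rounded; display formatting rounds sums to one
decimal and differences ≥ 50 million to the nearest million.

**Mid levels.** `interpolate_mid_levels` inserts a level between every
adjacent pair carrying the arithmetic mean of its neighbours, as a
sensitivity device for contested ratings. It preserves the score of every
rating expressed in original levels.

## Elicitation of point values

Questions pit two hypothetical technologies defined on two dimensions at a
time (all others held equal); the pool contains every genuine trade-off:
for dimensions with m₁…m_D levels, Σ_{i<j} C(m_i,2)·C(m_j,2) questions
(247 for the bundled 5/4/4/3/2 structure). Dominated comparisons are never
asked — they are pre-resolved.

Internally each profile is a level-index vector over all dimensions
(unmentioned dimensions at bottom), so transitivity chains across dimension
pairs. The closure over the ≤ 2-non-bottom-dimension universe is held as
per-node reachability bitmasks with weak (at-least-as-good) and strict
labels; dominance seeds the weak relation; every verdict adds an edge and
updates incrementally (all new relations pass through the new edge, so one
sweep over the edge's ancestors suffices). A verdict that would close a
cycle containing a strict edge raises an inconsistency error that reports
the judgments on the offending cycle.

Question order is adaptive: among open questions, pick the one whose answer
— whichever strict way it falls — resolves the most other open questions
(maximin information gain, ties by canonical enumeration order). A seeded
random order is available for order-independence testing. On the bundled
structure the greedy order asks 111 of 247 questions; the count is a
property of this heuristic, not a contract.

**Derivation.** With the pool fully resolved, level values come from a
linear program: bottom = 0, within-dimension monotonicity, for every strict
pool relation the two-dimension sums differ in the judged direction by at
least a slack `s`, equal verdicts as equalities, top values summing to 1;
maximize `s` (capped at 1 so the LP stays bounded when the session contains
no strict verdicts, e.g. all-equal answers). Any feasible solution with
`s > 0` ranks every pool pair exactly as the respondent did — the ordinal
recovery property the tests assert; the cap also fixes the degenerate
freedom when constraints are few. The published method's proprietary
derivation is different and unpublished in detail; this formulation is this
package's own, documented substitute with the same ordinal guarantees.

Simulated respondents answer by comparing hidden two-dimension sums at
integer micro-point (1e-6) resolution, making the oracle exactly transitive;
synthetic hidden schedules are generated on a 1e-4 grid so this scaling is
lossless.

## Portfolio analysis

**Frontier.** Dominance is weak-with-one-strict; exact (cost, benefit) ties
are all retained. Implementation is an O(n log n) cost-sorted sweep,
checked in tests against the O(n²) definition. Frontier output is sorted by
cost then benefit, and is strictly upward-sloping when there are no exact
ties. The point with the largest benefit/cost ratio always lies on the
frontier (if something dominated it, that dominator would have a strictly
larger ratio).

**Selection.** `SelectionState` is immutable; `select` conserves
`spent + unallocated = budget` and refuses to overspend unless forced
(recording a deliberate committee override).

**Knapsack.** Costs are scaled ×100 (two-decimal precision, matching the
fixture table) and benefits ×1e6 to integers; a suffix DP maximizes
(total benefit, −total cost), and reconstruction prefers including the
lexicographically earliest id whenever an optimal completion allows it,
which yields the lexicographically smallest optimal id set. If the budget
covers every candidate, everything not locked out is returned. The DP is
the benchmark only — X-factors are handled as lock constraints, never as
objective terms, and the tool reports rather than decides.

**What-would-it-take.** Upgrade combinations are searched exhaustively in
order of (number of dimensions changed, score increase); the first set
making the re-scored technology non-dominated is returned. Costs are never
varied: the question concerns uncertainty in benefit ratings only.

**Shortlist.** Nomination counts > n/2 are majority; ≥ 1 but not majority
are question-marked; both sorted by support.

## Chart

Structural SVG, emitted directly: `circle.bubble` per technology (class
`xfactor` when flagged), `polyline.frontier`, two `line.quadrant-guide`
elements, axis labels, per-bubble id labels. Evidence maps linearly to
bubble *area* (1:2:3). Quadrant guides default to the midrange of the
plotted costs and benefits — the plane's quadrant split is a reading aid
with no canonical definition, so absolute overrides are provided. A
grayscale-safe hatch replaces the highlight color on request. SVG is the
canonical artifact; no raster export is provided.

## Synthetic data

The generator emulates a submission round: log-normal annual costs
(`exp(N(3.0, 1.0))` millions, i.e. a median near 20 with a long right tail
spanning the bundled table's 3–124 range), uniform ratings per dimension
unless weights are given, evidence drawn (0.10, 0.25, 0.65) over
poor/medium/high and an X-factor probability of 0.30 — both matching the
bundled table's frequencies (1/4/13 grades, 5/18 X-factors). It does not
model correlation between benefit and cost, eligibility-driven patient
counts, or year-to-year resubmission, so passing property tests show
algorithmic correctness on realistic marginals, not calibrated realism of
joint structure.

## Problem sizes and numerical choices

Property suites run at desk scale: 200 random portfolios (n ≤ 50) for the
frontier oracle, 50 portfolios (n ≤ 12) against exhaustive knapsack
enumeration, 20 random hidden schedules (3–5 dimensions, 2–5 levels) for
full elicitation recovery — all chosen as the smallest sizes that exercise
every code path and tie-break. LP solving uses HiGHS; derived values are
rounded to 9 decimals and clamped monotone to scrub solver tolerance.

## Known limitations

- The elicitation derivation is one consistent schedule among many; only
  the ordinal pool ranking is identified by a session, not cardinal values.
- Group processes (voting on each question, preference aggregation across
  respondents) are out of scope; the session consumes a single judgment
  stream, e.g. a consensus answer.
- Quadrant thresholds, bubble-area mapping and display rounding are
  presentation conventions, configurable but with no claim of canonicity.
- Mixed cost conventions (NPV vs per-annum) in one table are not converted;
  the loader trusts the declared metadata.
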