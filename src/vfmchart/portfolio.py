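"""Portfolio analysis: value-for-money points, Pareto frontiers, budget
selection, an exact knapsack benchmark, and deliberation aids.

Each candidate technology carries four separate variables: a benefit rating
(scored additively by the points system), an annual total cost in millions,
an ordinal quality-of-evidence grade, and free-text "X-factors".  Evidence
and X-factors never enter the benefit score or the knapsack objective — they
are display attributes and, for X-factors, possible lock-in/lock-out
overrides of the budget optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations, product
from typing import Iterable, Mapping, Optional, Sequence

from .points import PointsSystem, Rating, max_score, normalize_label, total_score

__all__ = [
    "EVIDENCE_GRADES",
    "Technology",
    "VfMPoint",
    "SelectionState",
    "CommitteeBallot",
    "WhatIfResult",
    "PortfolioError",
    "UnknownTechnologyError",
    "BudgetExceededError",
    "build_vfm_points",
    "pareto_frontier",
    "compare_costs",
    "new_selection",
    "select",
    "knapsack_optimal",
    "what_would_it_take",
    "committee_shortlist",
    "format_millions",
]

EVIDENCE_GRADES = ("poor", "medium", "high")

#: Costs are meaningful to Table-2 precision (two decimals of a million);
#: the knapsack DP scales by this to exact integers.
COST_SCALE = 100
#: Benefit scores are scaled to integers at micro-point resolution inside the
#: knapsack DP so optima and ties are exact.
_BENEFIT_SCALE = 10**6


class PortfolioError(Exception):
    pass


class UnknownTechnologyError(PortfolioError):
    pass


class BudgetExceededError(PortfolioError):
    pass


@dataclass(frozen=True)
class Technology:
    """One candidate technology (a row of the technology table)."""

    id: str
    name: str
    rating: Rating
    total_cost: float  # millions of currency per annum
    evidence: str = "medium"
    indication: str = ""
    n_patients: int = 0
    x_factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_factors", tuple(self.x_factors))
        if self.evidence not in EVIDENCE_GRADES:
            raise PortfolioError(
                f"technology {self.id!r}: evidence grade must be one of "
                f"{EVIDENCE_GRADES}, got {self.evidence!r}"
            )
        if not (self.total_cost >= 0 and self.total_cost < float("inf")):
            raise PortfolioError(
                f"technology {self.id!r}: total_cost must be finite and >= 0"
            )
        if self.n_patients < 0:
            raise PortfolioError(f"technology {self.id!r}: n_patients must be >= 0")


@dataclass(frozen=True)
class VfMPoint:
    """A technology projected onto the chart axes: (benefit, cost) plus
    evidence grade and an X-factor flag."""

    tech_id: str
    benefit: float
    cost: float
    evidence: str = "medium"
    x_flag: bool = False


@dataclass(frozen=True)
class CommitteeBallot:
    member_id: str
    nominations: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nominations", frozenset(self.nominations))


@dataclass(frozen=True)
class WhatIfResult:
    """Outcome of a what-would-it-take search.

    ``status`` is ``"on_frontier"`` (no change needed), ``"upgrade"``
    (``upgrades`` maps dimension name to the new level label), or
    ``"not_achievable"`` (dominated even at the top rating).
    """

    status: str
    upgrades: Mapping[str, str] = field(default_factory=dict)


def build_vfm_points(
    techs: Sequence[Technology], ps: PointsSystem
) -> list[VfMPoint]:
    """Score every technology and project it to a chart point.

    ``x_flag`` is True iff the technology has any X-factor notes.
    """
    return [
        VfMPoint(
            tech_id=t.id,
            benefit=total_score(t.rating, ps),
            cost=t.total_cost,
            evidence=t.evidence,
            x_flag=bool(t.x_factors),
        )
        for t in techs
    ]


def pareto_frontier(points: Sequence[VfMPoint]) -> list[str]:
    """Ids of the non-dominated points, sorted by cost then benefit.

    A point is dominated if another point has cost <= and benefit >= with at
    least one strict inequality.  Points with identical (cost, benefit) do
    not dominate each other, so exact ties are all retained (they appear
    adjacent in the result).  Sort-and-sweep, O(n log n).
    """
    if not points:
        return []
    orderd = sorted(points, key=lambda p: (p.cost, p.benefit, p.tech_id))
    out: list[str] = []
    best_lt = float("-inf")  # max benefit among strictly cheaper points
    i = 0
    n = len(orderd)
    while i < n:
        j = i
        while j < n and orderd[j].cost == orderd[i].cost:
            j += 1
        group = orderd[i:j]
        group_max = max(p.benefit for p in group)
        for p in group:
            if p.benefit == group_max and p.benefit > best_lt:
                out.append(p.tech_id)
        best_lt = max(best_lt, group_max)
        i = j
    return out


def compare_costs(
    a: str, b: str, techs: Sequence[Technology]
) -> float:
    """Signed cost difference (millions): cost of ``a`` minus cost of ``b``."""
    costs = {t.id: t.total_cost for t in techs}
    for tid in (a, b):
        if tid not in costs:
            raise UnknownTechnologyError(f"unknown technology id {tid!r}")
    return costs[a] - costs[b]


@dataclass(frozen=True)
class SelectionState:
    """State of the deliberation loop: what's chosen, spent and still open."""

    budget: float
    selected: tuple[str, ...]
    spent: float
    remaining: frozenset[str]
    costs: Mapping[str, float] = field(repr=False)

    @property
    def unallocated(self) -> float:
        return self.budget - self.spent


def new_selection(techs: Sequence[Technology], budget: float) -> SelectionState:
    costs = {t.id: t.total_cost for t in techs}
    if len(costs) != len(techs):
        raise PortfolioError("technology ids must be unique in a portfolio")
    return SelectionState(
        budget=float(budget),
        selected=(),
        spent=0.0,
        remaining=frozenset(costs),
        costs=costs,
    )


def select(
    state: SelectionState, ids: Sequence[str], force: bool = False
) -> SelectionState:
    """Move ``ids`` from remaining to selected, updating the spent total.

    Exceeding the budget raises :class:`BudgetExceededError` unless
    ``force=True`` (an explicit committee override).
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise PortfolioError("duplicate ids in selection")
    for tid in ids:
        if tid in state.selected:
            raise PortfolioError(f"technology {tid!r} already selected")
        if tid not in state.remaining:
            raise UnknownTechnologyError(f"unknown technology id {tid!r}")
    added = sum(state.costs[tid] for tid in ids)
    spent = state.spent + added
    if spent > state.budget and not force:
        raise BudgetExceededError(
            f"selection would spend {spent:.2f} of a {state.budget:.2f} budget"
        )
    return replace(
        state,
        selected=state.selected + tuple(ids),
        spent=spent,
        remaining=state.remaining - set(ids),
    )


def knapsack_optimal(
    points: Sequence[VfMPoint],
    budget: float,
    locked_in: Iterable[str] = (),
    locked_out: Iterable[str] = (),
) -> set[str]:
    """Exact 0-1 knapsack: the feasible subset with maximal total benefit.

    Locked-in ids are always included (their cost is charged up front),
    locked-out ids never.  Among benefit-optimal subsets the one with
    minimal total cost is returned, ties broken toward the lexicographically
    smallest id set.  Costs are scaled to integers at two-decimal precision
    and benefits at micro-point precision, so the dynamic program is exact.
    """
    locked_in, locked_out = set(locked_in), set(locked_out)
    if locked_in & locked_out:
        raise PortfolioError("locked_in and locked_out overlap")
    by_id = {p.tech_id: p for p in points}
    for tid in locked_in | locked_out:
        if tid not in by_id:
            raise UnknownTechnologyError(f"unknown technology id {tid!r}")

    cap = round(budget * COST_SCALE)
    locked_cost = sum(round(by_id[t].cost * COST_SCALE) for t in locked_in)
    if locked_cost > cap:
        raise BudgetExceededError("locked-in technologies already exceed the budget")
    cap -= locked_cost

    items = sorted(
        (p for p in points if p.tech_id not in locked_in | locked_out),
        key=lambda p: p.tech_id,
    )
    if sum(round(p.cost * COST_SCALE) for p in items) <= cap:
        return {p.tech_id for p in items} | locked_in
    costs = [round(p.cost * COST_SCALE) for p in items]
    vals = [round(p.benefit * _BENEFIT_SCALE) for p in items]

    # dp[i][w]: best (value, -cost) using items i.. within capacity w
    n = len(items)
    NEG = (-1, 0)
    dp = [[NEG] * (cap + 1) for _ in range(n + 1)]
    dp[n] = [(0, 0)] * (cap + 1)
    for i in range(n - 1, -1, -1):
        ci, vi = costs[i], vals[i]
        skip_row, take_row = dp[i + 1], dp[i]
        for w in range(cap + 1):
            best = skip_row[w]
            if ci <= w:
                tv, tc = skip_row[w - ci]
                cand = (tv + vi, tc - ci)
                if cand > best:
                    best = cand
            take_row[w] = best

    # reconstruct, preferring inclusion of lexicographically earlier ids
    # whenever an optimal completion includes them
    chosen: set[str] = set(locked_in)
    w = cap
    for i in range(n):
        ci, vi = costs[i], vals[i]
        if ci <= w:
            tv, tc = dp[i + 1][w - ci]
            if (tv + vi, tc - ci) == dp[i][w] and (tv + vi, tc - ci) >= dp[i + 1][w]:
                chosen.add(items[i].tech_id)
                w -= ci
                continue
        # item i excluded; dp[i][w] must equal dp[i+1][w]
    return chosen


def what_would_it_take(
    tech_id: str,
    techs: Sequence[Technology],
    ps: PointsSystem,
) -> WhatIfResult:
    """Smallest set of single-dimension rating upgrades putting a technology
    on the Pareto frontier.

    Searches upgrade combinations exhaustively, ordered by the number of
    dimensions changed and then by the total score increase, so the first
    hit is the least drastic what-if scenario.  Costs are never varied: the
    question concerns uncertainty in the benefit ratings.
    """
    by_id = {t.id: t for t in techs}
    if tech_id not in by_id:
        raise UnknownTechnologyError(f"unknown technology id {tech_id!r}")
    target = by_id[tech_id]
    points = build_vfm_points(techs, ps)

    def non_dominated(benefit: float) -> bool:
        probe = [
            p if p.tech_id != tech_id else replace(p, benefit=benefit)
            for p in points
        ]
        return tech_id in pareto_frontier(probe)

    base = total_score(target.rating, ps)
    if non_dominated(base):
        return WhatIfResult(status="on_frontier")

    norm_assign = {
        normalize_label(k): v for k, v in target.rating.assignments.items()
    }
    current_idx = {
        d.name: d.index_of(norm_assign[normalize_label(d.name)])
        for d in ps.dimensions
    }

    upgradable = [
        d for d in ps.dimensions if current_idx[d.name] < len(d.levels) - 1
    ]
    candidates: list[tuple[int, float, dict[str, str]]] = []
    for k in range(1, len(upgradable) + 1):
        for dims in combinations(upgradable, k):
            level_choices = [
                range(current_idx[d.name] + 1, len(d.levels)) for d in dims
            ]
            for pick in product(*level_choices):
                delta = sum(
                    d.levels[l].point_value - d.levels[current_idx[d.name]].point_value
                    for d, l in zip(dims, pick)
                )
                candidates.append(
                    (k, delta, {d.name: d.levels[l].label for d, l in zip(dims, pick)})
                )
    candidates.sort(key=lambda c: (c[0], c[1]))
    for k, delta, upgrades in candidates:
        if non_dominated(base + delta):
            return WhatIfResult(status="upgrade", upgrades=upgrades)
    return WhatIfResult(status="not_achievable")


def committee_shortlist(
    ballots: Sequence[CommitteeBallot],
    n_members: int,
    top_k: Optional[int] = None,
) -> tuple[list[str], list[str]]:
    """Tally 'top ten'-style nominations into a shortlist.

    Technologies nominated by a strict majority of members go on the
    majority list; those nominated by at least one member but not a majority
    are question-marked.  Both lists are sorted by nomination count
    descending (ties by id).  ``top_k`` optionally enforces the per-ballot
    nomination cap.
    """
    if n_members < 1:
        raise PortfolioError("n_members must be >= 1")
    seen_members: set[str] = set()
    counts: dict[str, int] = {}
    for b in ballots:
        if b.member_id in seen_members:
            raise PortfolioError(f"duplicate ballot from member {b.member_id!r}")
        seen_members.add(b.member_id)
        if top_k is not None and len(b.nominations) > top_k:
            raise PortfolioError(
                f"ballot from {b.member_id!r} nominates more than {top_k}"
            )
        for tid in b.nominations:
            counts[tid] = counts.get(tid, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    majority = [tid for tid, c in ranked if c > n_members / 2]
    marked = [tid for tid, c in ranked if 0 < c <= n_members / 2]
    return majority, marked


def format_millions(value: float, *, difference: bool = False) -> str:
    """Display rounding for costs in millions.

    Sums and small figures print to one decimal; differences of 50 million
    or more are quoted to the nearest million ("approximately 98 million").
    Raw values are never rounded internally — this is display only.
    """
    if difference and abs(value) >= 50:
        return f"{value:.0f}"
    return f"{value:.1f}"
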