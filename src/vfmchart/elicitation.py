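"""Pairwise-ranking elicitation of point values (PAPRIKA-style).

Point values are elicited by asking a decision-maker to rank pairs of
hypothetical technologies defined on **two dimensions at a time**, all other
dimensions held equal.  Each question is a genuine trade-off: the left
profile is strictly better on one dimension and strictly worse on the other,
so no question can be settled by dominance alone.

Answered questions propagate through the *transitive closure* of the
preference relation (if A > B and B > C then A > C), together with dominance
(a profile at least as good on both dimensions is weakly preferred), so that
implied questions are never asked.  Once the whole question pool is resolved
the session is converted into a concrete points schedule by
:func:`derive_point_values`: a linear program that maximizes the minimum
margin by which the elicited strict preferences are respected, normalizing
the sum of top-level values to 1.

Profiles are represented internally as level-index vectors over all
dimensions (unmentioned dimensions sit at the bottom level), which lets
transitivity chain across different dimension pairs: the profile "dimension
j at level b, everything else bottom" is the same node whether it arose from
a (i, j) question or a (j, k) question.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Iterator, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .points import (
    Dimension,
    Level,
    PointsSystem,
    points_system_from_dict,
    points_system_to_dict,
    validate_points_system,
)

__all__ = [
    "TradeoffProfile",
    "PairwiseQuestion",
    "Judgment",
    "RankingState",
    "InconsistencyError",
    "DerivationError",
    "enumerate_tradeoff_pairs",
    "simulate_answers",
    "run_session",
    "derive_point_values",
    "pool_agreement",
]

LEFT = "left"
RIGHT = "right"
EQUAL = "equal"

#: Integer scaling used when a hidden points system answers questions, so the
#: simulated oracle compares sums exactly and is therefore transitive.
_ORACLE_SCALE = 10**6


class InconsistencyError(Exception):
    """A judgment would create a strict preference cycle.

    ``judgments`` holds the previously recorded judgments on the offending
    cycle (plus the new one), so the contradiction can be shown to the
    respondent.
    """

    def __init__(self, message: str, judgments: Sequence["Judgment"] = ()):
        super().__init__(message)
        self.judgments = list(judgments)


class DerivationError(Exception):
    """The elicited constraint set admits no consistent points schedule."""


@dataclass(frozen=True)
class TradeoffProfile:
    """A hypothetical technology described on two dimensions only."""

    dim_a: str
    level_a: str
    dim_b: str
    level_b: str


@dataclass(frozen=True)
class PairwiseQuestion:
    """Two trade-off profiles on the same dimension pair to be ranked."""

    left: TradeoffProfile
    right: TradeoffProfile


@dataclass(frozen=True)
class Judgment:
    question: PairwiseQuestion
    verdict: str  # one of "left", "right", "equal"


def _pool_tuples(ps: PointsSystem) -> Iterator[tuple[int, int, int, int, int, int]]:
    """Canonical enumeration: (i, j, a1, a2, b1, b2) with i<j, a1<a2, b1<b2.

    The question pits (i at a2, j at b1) against (i at a1, j at b2): the left
    profile is better on dimension i, worse on dimension j.
    """
    nd = len(ps.dimensions)
    for i, j in combinations(range(nd), 2):
        mi = len(ps.dimensions[i].levels)
        mj = len(ps.dimensions[j].levels)
        for a1, a2 in combinations(range(mi), 2):
            for b1, b2 in combinations(range(mj), 2):
                yield (i, j, a1, a2, b1, b2)


def enumerate_tradeoff_pairs(ps: PointsSystem) -> list[PairwiseQuestion]:
    """Every genuine two-dimension trade-off question, in canonical order.

    For each unordered dimension pair (i, j) and each pair of levels within
    each dimension there is exactly one question, so the pool size is
    ``sum over i<j of C(m_i, 2) * C(m_j, 2)``.
    """
    out = []
    dims = ps.dimensions
    for i, j, a1, a2, b1, b2 in _pool_tuples(ps):
        di, dj = dims[i], dims[j]
        out.append(
            PairwiseQuestion(
                left=TradeoffProfile(
                    di.name, di.levels[a2].label, dj.name, dj.levels[b1].label
                ),
                right=TradeoffProfile(
                    di.name, di.levels[a1].label, dj.name, dj.levels[b2].label
                ),
            )
        )
    return out


class RankingState:
    """An elicitation session: judgments plus their transitive closure.

    The closure is kept as per-node reachability bitmasks over the universe
    of profiles with at most two non-bottom dimensions: ``weak[u]`` holds v
    iff u is at-least-as-good-as v (via dominance, "equal" verdicts and
    chains), ``strict[u]`` holds v iff some chain from u to v contains a
    strict judgment.  Dominance seeds the weak relation; every update is
    incremental (new relations all pass through the newly added edge).
    """

    def __init__(self, structure: PointsSystem):
        self.structure = structure
        dims = structure.dimensions
        self._sizes = [len(d.levels) for d in dims]
        nd = len(dims)

        # node universe: all level-index vectors with <= 2 non-bottom entries
        nodes: list[tuple[int, ...]] = [tuple([0] * nd)]
        for i in range(nd):
            for a in range(1, self._sizes[i]):
                vec = [0] * nd
                vec[i] = a
                nodes.append(tuple(vec))
        for i, j in combinations(range(nd), 2):
            for a in range(1, self._sizes[i]):
                for b in range(1, self._sizes[j]):
                    vec = [0] * nd
                    vec[i], vec[j] = a, b
                    nodes.append(tuple(vec))
        self._nodes = nodes
        self._index = {v: k for k, v in enumerate(nodes)}
        n = len(nodes)

        # dominance closure seeds weak reachability (componentwise >=)
        self._weak = [0] * n
        self._rweak = [0] * n
        for u in range(n):
            for v in range(n):
                if all(a >= b for a, b in zip(nodes[u], nodes[v])):
                    self._weak[u] |= 1 << v
                    self._rweak[v] |= 1 << u
        self._strict = [0] * n

        self._pool: list[tuple[int, int, PairwiseQuestion]] = []
        for q in enumerate_tradeoff_pairs(structure):
            self._pool.append((*self._question_nodes(q), q))
        self._unresolved: list[int] = list(range(len(self._pool)))
        # symmetric partner masks of unresolved pool pairs, for greedy scoring
        self._pairmask: dict[int, int] = {}
        for k in self._unresolved:
            L, R, _ = self._pool[k]
            self._pairmask[L] = self._pairmask.get(L, 0) | (1 << R)
            self._pairmask[R] = self._pairmask.get(R, 0) | (1 << L)

        self.answered: list[Judgment] = []
        # direct judgment edges, for cycle reporting: (u, v) -> Judgment
        self._edges: dict[tuple[int, int], Judgment] = {}

    # -- profile/node plumbing ---------------------------------------------

    def _profile_vec(self, p: TradeoffProfile) -> tuple[int, ...]:
        vec = [0] * len(self._sizes)
        da = self.structure.dimension(p.dim_a)
        db = self.structure.dimension(p.dim_b)
        ia = self.structure.dimensions.index(da)
        ib = self.structure.dimensions.index(db)
        if ia == ib:
            raise ValueError("profile must span two distinct dimensions")
        vec[ia] = da.index_of(p.level_a)
        vec[ib] = db.index_of(p.level_b)
        return tuple(vec)

    def _question_nodes(self, q: PairwiseQuestion) -> tuple[int, int]:
        return self._index[self._profile_vec(q.left)], self._index[
            self._profile_vec(q.right)
        ]

    @property
    def pool(self) -> list[PairwiseQuestion]:
        return [q for _, _, q in self._pool]

    @property
    def pool_size(self) -> int:
        return len(self._pool)

    @property
    def n_unresolved(self) -> int:
        return len(self._unresolved)

    @property
    def done(self) -> bool:
        return not self._unresolved

    def resolution(self, q: PairwiseQuestion) -> Optional[str]:
        """Closure's verdict for a question, or None if still open."""
        L, R = self._question_nodes(q)
        return self._resolution_idx(L, R)

    def _resolution_idx(self, L: int, R: int) -> Optional[str]:
        if self._strict[L] >> R & 1:
            return LEFT
        if self._strict[R] >> L & 1:
            return RIGHT
        if (self._weak[L] >> R & 1) and (self._weak[R] >> L & 1):
            return EQUAL
        return None

    # -- closure updates ----------------------------------------------------

    def _iter_bits(self, mask: int) -> Iterator[int]:
        while mask:
            low = mask & -mask
            yield low.bit_length() - 1
            mask ^= low

    def _add_weak(self, L: int, R: int) -> None:
        wr, sr = self._weak[R], self._strict[R]
        rl = self._rweak[L]
        for u in self._iter_bits(rl):
            if self._strict[u] >> L & 1:
                self._strict[u] |= wr
            else:
                self._strict[u] |= sr
            self._weak[u] |= wr
        for v in self._iter_bits(wr):
            self._rweak[v] |= rl

    def _add_strict(self, L: int, R: int) -> None:
        wr = self._weak[R]
        rl = self._rweak[L]
        for u in self._iter_bits(rl):
            self._weak[u] |= wr
            self._strict[u] |= wr
        for v in self._iter_bits(wr):
            self._rweak[v] |= rl

    def _cycle_judgments(self, src: int, dst: int) -> list[Judgment]:
        """Judgments along some weak path src -> dst (BFS over direct edges)."""
        parent: dict[int, tuple[int, Optional[Judgment]]] = {src: (src, None)}
        frontier = [src]
        nodes = self._nodes
        while frontier and dst not in parent:
            nxt = []
            for u in frontier:
                # dominance steps
                for v in self._iter_bits(self._weak[u]):
                    if v not in parent and all(
                        a >= b for a, b in zip(nodes[u], nodes[v])
                    ):
                        parent[v] = (u, None)
                        nxt.append(v)
                # judgment edges
                for (a, b), j in self._edges.items():
                    if a == u and b not in parent:
                        parent[b] = (u, j)
                        nxt.append(b)
            frontier = nxt
        out = []
        cur = dst
        while cur != src:
            cur, j = parent.get(cur, (src, None))
            if j is not None:
                out.append(j)
        return out[::-1]

    # -- the elicitation API ------------------------------------------------

    def record_judgment(self, judgment: Judgment) -> "RankingState":
        """Add a verdict, propagate the closure, and verify consistency.

        Raises :class:`InconsistencyError` when the verdict would close a
        strict preference cycle, reporting the judgments on the cycle.
        Re-answering a question whose verdict is already set or implied is a
        ``ValueError`` (the question would never have been asked).
        """
        L, R = self._question_nodes(judgment.question)
        if self._resolution_idx(L, R) is not None:
            raise ValueError("question is already resolved (answered or implied)")
        v = judgment.verdict
        if v not in (LEFT, RIGHT, EQUAL):
            raise ValueError(f"unknown verdict {v!r}")
        if v == LEFT and (self._weak[R] >> L & 1):
            raise InconsistencyError(
                "verdict 'left' contradicts an implied weak preference "
                "right-over-left",
                self._cycle_judgments(R, L) + [judgment],
            )
        if v == RIGHT and (self._weak[L] >> R & 1):
            raise InconsistencyError(
                "verdict 'right' contradicts an implied weak preference "
                "left-over-right",
                self._cycle_judgments(L, R) + [judgment],
            )
        if v == EQUAL and (
            (self._strict[L] >> R & 1) or (self._strict[R] >> L & 1)
        ):
            a, b = (L, R) if (self._strict[L] >> R & 1) else (R, L)
            raise InconsistencyError(
                "verdict 'equal' contradicts an implied strict preference",
                self._cycle_judgments(a, b) + [judgment],
            )

        if v == LEFT:
            self._add_strict(L, R)
            self._edges[(L, R)] = judgment
        elif v == RIGHT:
            self._add_strict(R, L)
            self._edges[(R, L)] = judgment
        else:
            self._add_weak(L, R)
            self._add_weak(R, L)
            self._edges[(L, R)] = judgment
            self._edges[(R, L)] = judgment
        self.answered.append(judgment)

        still_open = []
        for k in self._unresolved:
            a, b, _ = self._pool[k]
            if self._resolution_idx(a, b) is None:
                still_open.append(k)
            else:
                self._pairmask[a] &= ~(1 << b)
                self._pairmask[b] &= ~(1 << a)
        self._unresolved = still_open
        return self

    def next_question(
        self,
        strategy: str = "greedy",
        rng: Optional[np.random.Generator] = None,
    ) -> Optional[PairwiseQuestion]:
        """An unresolved pool question, or None when the pool is resolved.

        ``"greedy"`` picks the question whose answer (whichever strict way it
        falls) is guaranteed to resolve the most still-open pool questions —
        a maximin information-gain heuristic; ties fall back to canonical
        pool order.  ``"random"`` draws uniformly (seeded ``rng`` required),
        ``"canonical"`` takes the first open question.
        """
        if not self._unresolved:
            return None
        if strategy == "canonical":
            return self._pool[self._unresolved[0]][2]
        if strategy == "random":
            if rng is None:
                rng = np.random.default_rng()
            k = self._unresolved[int(rng.integers(len(self._unresolved)))]
            return self._pool[k][2]
        if strategy != "greedy":
            raise ValueError(f"unknown strategy {strategy!r}")

        best_k, best_score = self._unresolved[0], -1
        for k in self._unresolved:
            L, R, _ = self._pool[k]
            gain_left = sum(
                (self._pairmask.get(a, 0) & self._weak[R]).bit_count()
                for a in self._iter_bits(self._rweak[L])
            )
            gain_right = sum(
                (self._pairmask.get(a, 0) & self._weak[L]).bit_count()
                for a in self._iter_bits(self._rweak[R])
            )
            score = min(gain_left, gain_right)
            if score > best_score:
                best_k, best_score = k, score
        return self._pool[best_k][2]

    # -- resolved relations --------------------------------------------------

    def pool_resolutions(self) -> list[tuple[PairwiseQuestion, Optional[str]]]:
        return [(q, self._resolution_idx(L, R)) for L, R, q in self._pool]

    # -- persistence ---------------------------------------------------------

    def to_json(self) -> str:
        """Serialize structure + judgments; reload resumes mid-session."""
        return json.dumps(
            {
                "structure": points_system_to_dict(self.structure),
                "judgments": [
                    {
                        "left": vars(j.question.left),
                        "right": vars(j.question.right),
                        "verdict": j.verdict,
                    }
                    for j in self.answered
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "RankingState":
        data = json.loads(text)
        state = cls(points_system_from_dict(data["structure"]))
        for j in data.get("judgments", []):
            state.record_judgment(
                Judgment(
                    PairwiseQuestion(
                        TradeoffProfile(**j["left"]), TradeoffProfile(**j["right"])
                    ),
                    j["verdict"],
                )
            )
        return state


def simulate_answers(hidden: PointsSystem) -> Callable[[PairwiseQuestion], str]:
    """Judgment oracle answering from a hidden points system.

    Two-dimension score sums are compared at micro-point integer resolution,
    so the oracle is exactly transitive and never triggers inconsistency
    errors; exact ties yield the "equal" verdict.
    """
    values = {
        d.name: {lv.label: round(lv.point_value * _ORACLE_SCALE) for lv in d.levels}
        for d in hidden.dimensions
    }

    def profile_sum(p: TradeoffProfile) -> int:
        return values[p.dim_a][p.level_a] + values[p.dim_b][p.level_b]

    def answer(q: PairwiseQuestion) -> str:
        ls, rs = profile_sum(q.left), profile_sum(q.right)
        if ls > rs:
            return LEFT
        if rs > ls:
            return RIGHT
        return EQUAL

    return answer


def run_session(
    structure: PointsSystem,
    oracle: Callable[[PairwiseQuestion], str],
    strategy: str = "greedy",
    rng: Optional[np.random.Generator] = None,
) -> RankingState:
    """Answer adaptively chosen questions until the whole pool is resolved."""
    state = RankingState(structure)
    while True:
        q = state.next_question(strategy=strategy, rng=rng)
        if q is None:
            return state
        state.record_judgment(Judgment(q, oracle(q)))


def derive_point_values(state: RankingState, slack_cap: float = 1.0) -> PointsSystem:
    """Turn a fully resolved session into a concrete points schedule.

    Solves a linear program over the level values: within-dimension
    monotonicity with bottom level 0; for every elicited or implied strict
    preference between pool profiles the two-dimension sums must differ in
    the judged direction by at least a slack ``s``; "equal" verdicts are
    equality constraints; the top-level values sum to 1.  The LP maximizes
    ``s`` (capped at ``slack_cap`` so it stays bounded when no strict
    constraint exists), yielding the schedule that respects the elicited
    ranking by the widest uniform margin.
    """
    if not state.done:
        raise ValueError(
            f"question pool not fully resolved ({state.n_unresolved} open)"
        )
    ps = state.structure
    dims = ps.dimensions

    var: dict[tuple[int, int], int] = {}
    for i, d in enumerate(dims):
        for l in range(1, len(d.levels)):
            var[(i, l)] = len(var)
    nvar = len(var) + 1  # + slack
    s_col = nvar - 1

    def profile_coeffs(p: TradeoffProfile) -> dict[int, float]:
        out: dict[int, float] = {}
        for dname, label in ((p.dim_a, p.level_a), (p.dim_b, p.level_b)):
            d = ps.dimension(dname)
            i = dims.index(d)
            l = d.index_of(label)
            if l > 0:
                c = var[(i, l)]
                out[c] = out.get(c, 0.0) + 1.0
        return out

    A_ub_rows, b_ub = [], []
    A_eq_rows, b_eq = [], []

    def row(coeffs: dict[int, float]) -> np.ndarray:
        r = np.zeros(nvar)
        for c, v in coeffs.items():
            r[c] = v
        return r

    for q, res in state.pool_resolutions():
        lc, rc = profile_coeffs(q.left), profile_coeffs(q.right)
        diff = {c: lc.get(c, 0.0) - rc.get(c, 0.0) for c in set(lc) | set(rc)}
        if res == LEFT:
            r = row({c: -v for c, v in diff.items()})
            r[s_col] = 1.0  # score(R) - score(L) + s <= 0
            A_ub_rows.append(r)
            b_ub.append(0.0)
        elif res == RIGHT:
            r = row(diff)
            r[s_col] = 1.0
            A_ub_rows.append(r)
            b_ub.append(0.0)
        elif res == EQUAL:
            A_eq_rows.append(row(diff))
            b_eq.append(0.0)
        else:  # pragma: no cover - guarded by state.done
            raise DerivationError("unresolved question in a done state")

    for i, d in enumerate(dims):
        for l in range(1, len(d.levels) - 1):
            r = np.zeros(nvar)
            r[var[(i, l)]] = 1.0
            r[var[(i, l + 1)]] = -1.0
            A_ub_rows.append(r)
            b_ub.append(0.0)

    norm = np.zeros(nvar)
    for i, d in enumerate(dims):
        norm[var[(i, len(d.levels) - 1)]] = 1.0
    A_eq_rows.append(norm)
    b_eq.append(1.0)

    c = np.zeros(nvar)
    c[s_col] = -1.0
    bounds = [(0.0, None)] * (nvar - 1) + [(0.0, float(slack_cap))]
    res = linprog(
        c,
        A_ub=np.array(A_ub_rows) if A_ub_rows else None,
        b_ub=np.array(b_ub) if b_ub else None,
        A_eq=np.array(A_eq_rows),
        b_eq=np.array(b_eq),
        bounds=bounds,
        method="highs",
    )
    if not res.success:
        raise DerivationError(
            f"no consistent points schedule exists for this session: {res.message}"
        )

    x = res.x
    new_dims = []
    for i, d in enumerate(dims):
        vals = [0.0]
        for l in range(1, len(d.levels)):
            v = round(max(0.0, float(x[var[(i, l)]])), 9)
            vals.append(max(v, vals[-1]))  # scrub solver-tolerance dips
        new_dims.append(
            Dimension(
                name=d.name,
                levels=tuple(
                    Level(label=lv.label, point_value=v)
                    for lv, v in zip(d.levels, vals)
                ),
            )
        )
    derived = PointsSystem(
        dimensions=tuple(new_dims),
        name=(ps.name + " (derived)").strip(),
        metadata={
            **ps.metadata,
            "derivation": "max-min-slack LP from pairwise rankings",
            "slack": f"{-res.fun:.6g}",
            "questions_asked": str(len(state.answered)),
            "pool_size": str(state.pool_size),
        },
    )
    assert not validate_points_system(derived)
    return derived


def pool_agreement(
    hidden: PointsSystem, derived: PointsSystem, atol: float = 1e-7
) -> bool:
    """Do two points systems rank every pool question identically?

    The hidden system is compared exactly (integer micro-points); the derived
    system with a small absolute tolerance, since its values come from an LP
    solver.
    """
    oracle = simulate_answers(hidden)

    dvals = {
        d.name: {lv.label: lv.point_value for lv in d.levels}
        for d in derived.dimensions
    }

    def derived_verdict(q: PairwiseQuestion) -> str:
        ls = dvals[q.left.dim_a][q.left.level_a] + dvals[q.left.dim_b][q.left.level_b]
        rs = (
            dvals[q.right.dim_a][q.right.level_a]
            + dvals[q.right.dim_b][q.right.level_b]
        )
        if ls > rs + atol:
            return LEFT
        if rs > ls + atol:
            return RIGHT
        return EQUAL

    return all(
        oracle(q) == derived_verdict(q) for q in enumerate_tradeoff_pairs(hidden)
    )
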