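"""Pairwise-ranking elicitation: question pool, closure, derivation."""

import itertools

import numpy as np
import pytest

from vfmchart import (
    Dimension,
    InconsistencyError,
    Judgment,
    Level,
    PointsSystem,
    RankingState,
    derive_point_values,
    enumerate_tradeoff_pairs,
    pool_agreement,
    run_session,
    simulate_answers,
    validate_points_system,
)
from vfmchart.elicitation import EQUAL, LEFT, RIGHT
from vfmchart.synth import random_points_system


def structure(*level_counts):
    """A bare points structure (values are placeholders)."""
    return PointsSystem(
        tuple(
            Dimension(
                f"d{i}",
                tuple(Level(f"l{j}", 0.01 * j) for j in range(m)),
            )
            for i, m in enumerate(level_counts)
        )
    )


def find_question(state, dim_a, la, dim_b, lb, la2, lb2):
    """The pool question pitting (dim_a=la vs la2, dim_b=lb vs lb2)."""
    for q in state.pool:
        if (
            q.left.dim_a == dim_a
            and q.left.level_a == la
            and q.left.level_b == lb
            and q.right.level_a == la2
            and q.right.level_b == lb2
            and q.left.dim_b == dim_b
        ):
            return q
    raise AssertionError("question not in pool")


class TestPool:
    def test_fixture_pool_has_247_questions(self, ps):
        assert len(enumerate_tradeoff_pairs(ps)) == 247

    @pytest.mark.parametrize(
        "levels, expected",
        [((2, 2), 1), ((2, 2, 2), 3), ((5, 4, 4, 3, 2), 247), ((3, 2), 3)],
    )
    def test_pool_size_formula(self, levels, expected):
        assert len(enumerate_tradeoff_pairs(structure(*levels))) == expected

    def test_questions_are_genuine_tradeoffs(self, ps):
        for q in enumerate_tradeoff_pairs(ps):
            assert q.left.dim_a == q.right.dim_a
            assert q.left.dim_b == q.right.dim_b
            da = ps.dimension(q.left.dim_a)
            db = ps.dimension(q.left.dim_b)
            # left strictly better on the first dimension, worse on the second
            assert da.index_of(q.left.level_a) > da.index_of(q.right.level_a)
            assert db.index_of(q.left.level_b) < db.index_of(q.right.level_b)


class TestClosure:
    def test_fresh_state_offers_a_question(self):
        state = RankingState(structure(2, 2, 2))
        q = state.next_question()
        assert q is not None and state.resolution(q) is None

    def test_transitive_chain_is_never_asked(self):
        # d0 top beats d1 top, d1 top beats d2 top => d0 vs d2 is implied
        state = RankingState(structure(2, 2, 2))
        q01 = find_question(state, "d0", "l1", "d1", "l0", "l0", "l1")
        q12 = find_question(state, "d1", "l1", "d2", "l0", "l0", "l1")
        q02 = find_question(state, "d0", "l1", "d2", "l0", "l0", "l1")
        state.record_judgment(Judgment(q01, LEFT))
        state.record_judgment(Judgment(q12, LEFT))
        assert state.resolution(q02) == LEFT
        assert state.next_question() is None and state.done

    def test_done_state_returns_no_question(self):
        state = RankingState(structure(2, 2))
        state.record_judgment(Judgment(state.next_question(), RIGHT))
        assert state.done and state.next_question() is None

    def test_reanswering_resolved_question_rejected(self):
        state = RankingState(structure(2, 2))
        q = state.next_question()
        state.record_judgment(Judgment(q, LEFT))
        with pytest.raises(ValueError, match="resolved"):
            state.record_judgment(Judgment(q, RIGHT))

    def test_equal_verdicts_propagate_interchangeably(self):
        # d0 two steps vs d1 one step: after l1(d0)=l1(d1), the profile
        # (d0:l2) weakly exceeds (d1:l1) via (d0:l1); contradicting that is
        # an inconsistency, confirming equals chain through dominance.
        state = RankingState(structure(3, 2))
        q1 = find_question(state, "d0", "l1", "d1", "l0", "l0", "l1")
        q2 = find_question(state, "d0", "l2", "d1", "l0", "l0", "l1")
        state.record_judgment(Judgment(q1, EQUAL))
        assert state.resolution(q2) is None
        with pytest.raises(InconsistencyError) as err:
            state.record_judgment(Judgment(q2, RIGHT))
        assert any(j.question == q1 for j in err.value.judgments)
        # the non-contradictory direction is still answerable
        state.record_judgment(Judgment(q2, LEFT))
        assert state.resolution(q2) == LEFT

    def test_closure_matches_brute_force_on_random_sessions(self):
        """Bitmask closure == label-aware Floyd-Warshall on small instances."""
        rng = np.random.default_rng(7)
        for trial in range(6):
            counts = tuple(int(m) for m in rng.integers(2, 5, size=int(rng.integers(2, 5))))
            struct = structure(*counts)
            # a hidden monotone value schedule on the same structure (ties
            # allowed via the rounding) drives the answers
            oracle_ps = PointsSystem(
                tuple(
                    Dimension(
                        d.name,
                        tuple(
                            Level(
                                lv.label,
                                round(k * (0.013 * (i + 1) + 0.007 * trial), 3),
                            )
                            for k, lv in enumerate(d.levels)
                        ),
                    )
                    for i, d in enumerate(struct.dimensions)
                )
            )
            oracle = simulate_answers(oracle_ps)
            state = RankingState(struct)
            # answer half the pool in random order
            order = list(state.pool)
            rng.shuffle(order)
            for q in order[: max(1, len(order) // 2)]:
                if state.resolution(q) is None:
                    state.record_judgment(Judgment(q, oracle(q)))
            assert_closure_matches_bruteforce(state, struct)


def assert_closure_matches_bruteforce(state, struct):
    """Recompute the closure by Floyd-Warshall over explicit relations."""
    sizes = [len(d.levels) for d in struct.dimensions]
    nd = len(sizes)
    nodes = [tuple([0] * nd)]
    for i in range(nd):
        for a in range(1, sizes[i]):
            v = [0] * nd
            v[i] = a
            nodes.append(tuple(v))
    for i, j in itertools.combinations(range(nd), 2):
        for a in range(1, sizes[i]):
            for b in range(1, sizes[j]):
                v = [0] * nd
                v[i], v[j] = a, b
                nodes.append(tuple(v))
    idx = {v: k for k, v in enumerate(nodes)}
    n = len(nodes)
    NONE, WEAK, STRICT = 0, 1, 2
    rel = [[NONE] * n for _ in range(n)]
    for u in range(n):
        for v in range(n):
            if u != v and all(a >= b for a, b in zip(nodes[u], nodes[v])):
                rel[u][v] = WEAK

    def vec(profile):
        out = [0] * nd
        for dname, label in (
            (profile.dim_a, profile.level_a),
            (profile.dim_b, profile.level_b),
        ):
            d = struct.dimension(dname)
            out[struct.dimensions.index(d)] = d.index_of(label)
        return tuple(out)

    for j in state.answered:
        L, R = idx[vec(j.question.left)], idx[vec(j.question.right)]
        if j.verdict == LEFT:
            rel[L][R] = STRICT
        elif j.verdict == RIGHT:
            rel[R][L] = STRICT
        else:
            rel[L][R] = max(rel[L][R], WEAK)
            rel[R][L] = max(rel[R][L], WEAK)
    for k in range(n):
        for u in range(n):
            if rel[u][k]:
                row_u, row_k = rel[u], rel[k]
                for v in range(n):
                    if row_k[v]:
                        through = STRICT if (row_u[k] == STRICT or row_k[v] == STRICT) else WEAK
                        row_u[v] = max(row_u[v], through)
    for q in state.pool:
        L, R = idx[vec(q.left)], idx[vec(q.right)]
        if rel[L][R] == STRICT:
            expected = LEFT
        elif rel[R][L] == STRICT:
            expected = RIGHT
        elif rel[L][R] == WEAK and rel[R][L] == WEAK:
            expected = EQUAL
        else:
            expected = None
        assert state.resolution(q) == expected, (q, expected)


class TestSimulatedOracle:
    def test_oracle_answers_from_printed_values(self, ps):
        # few lives saved (0.091) at bottom QoL, vs large QoL gains (0.217)
        # at bottom lives: the QoL side wins
        oracle = simulate_answers(ps)
        state = RankingState(ps)
        q = find_question(
            state,
            "Lives saved",
            "Few: 1-50 lives saved",
            "Quality-of-life (QoL) gains",
            "None/Very small (or not yet known)",
            "None (or not yet known)",
            "Large QoL gains",
        )
        assert oracle(q) == RIGHT

    def test_exact_ties_answer_equal(self):
        tied = PointsSystem(
            (
                Dimension("a", (Level("a0", 0.0), Level("a1", 0.2))),
                Dimension("b", (Level("b0", 0.0), Level("b1", 0.2))),
            )
        )
        oracle = simulate_answers(tied)
        [q] = enumerate_tradeoff_pairs(tied)
        assert oracle(q) == EQUAL

    def test_consistent_oracle_never_trips_inconsistency(self, ps):
        # random answer orders from a transitive oracle must always complete
        oracle = simulate_answers(ps)
        for seed in (0, 1):
            state = run_session(
                ps, oracle, strategy="random", rng=np.random.default_rng(seed)
            )
            assert state.done


class TestDerivation:
    def test_requires_completed_pool(self):
        state = RankingState(structure(2, 2))
        with pytest.raises(ValueError, match="not fully resolved"):
            derive_point_values(state)

    def test_single_tradeoff_orders_the_tops(self):
        state = RankingState(structure(2, 2))
        q = state.next_question()
        # make d0's upgrade the winner regardless of which side it is on
        winner = LEFT if q.left.dim_a == "d0" and q.left.level_a == "l1" else RIGHT
        state.record_judgment(Judgment(q, winner))
        derived = derive_point_values(state)
        v0 = derived.dimension("d0").top_value
        v1 = derived.dimension("d1").top_value
        assert v0 > v1
        assert v0 + v1 == pytest.approx(1.0)

    def test_all_equal_answers_give_equal_tops(self):
        state = RankingState(structure(2, 2, 2))
        while not state.done:
            state.record_judgment(Judgment(state.next_question(), EQUAL))
        derived = derive_point_values(state)
        tops = [d.top_value for d in derived.dimensions]
        assert tops == pytest.approx([1 / 3] * 3)

    def test_recovery_of_the_fixture_schedule(self, ps):
        oracle = simulate_answers(ps)
        state = run_session(ps, oracle)
        assert len(state.answered) < state.pool_size
        derived = derive_point_values(state)
        assert validate_points_system(derived) == []
        assert pool_agreement(ps, derived)

    def test_order_independence_of_closure_and_values(self):
        hidden = random_points_system(np.random.default_rng(11), n_dimensions=3)
        oracle = simulate_answers(hidden)
        outcomes = []
        for seed in (101, 202):
            state = run_session(
                hidden, oracle, strategy="random", rng=np.random.default_rng(seed)
            )
            res = [r for _, r in state.pool_resolutions()]
            derived = derive_point_values(state)
            values = [
                lv.point_value for d in derived.dimensions for lv in d.levels
            ]
            outcomes.append((res, values))
        assert outcomes[0][0] == outcomes[1][0]
        assert outcomes[0][1] == pytest.approx(outcomes[1][1], abs=1e-7)


class TestPersistence:
    def test_session_roundtrip_resumes(self, ps):
        oracle = simulate_answers(ps)
        state = RankingState(ps)
        for _ in range(10):
            q = state.next_question()
            state.record_judgment(Judgment(q, oracle(q)))
        resumed = RankingState.from_json(state.to_json())
        assert [r for _, r in resumed.pool_resolutions()] == [
            r for _, r in state.pool_resolutions()
        ]
        while not resumed.done:
            q = resumed.next_question()
            resumed.record_judgment(Judgment(q, oracle(q)))
        assert pool_agreement(ps, derive_point_values(resumed))
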