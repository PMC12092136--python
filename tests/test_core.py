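"""Unit and property tests for profiles, graphs and acceptability."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nashnets import (
    EquilibriumPolicy,
    Game,
    GameSpec,
    IsolatedRule,
    LabeledGraph,
    StrategyProfile,
    best_shot_payoff,
    check_acceptable,
    is_vertex_satisfied,
    neighbor_split,
    vertex_pairs,
)
from nashnets.core import make_mask_checker
from nashnets.errors import (
    DomainError,
    InputError,
    UnsupportedGameError,
)

from conftest import oracle_acceptable


class TestStrategyProfile:
    def test_partition(self):
        p = StrategyProfile((1, 0, 1, 1, 0, 0))
        assert p.n == 6
        assert p.n0 == 3 and p.n1 == 3
        assert p.V1 == {1, 3, 4}
        assert p.V0 == {2, 5, 6}
        assert p.n == p.n0 + p.n1
        assert p.V0 | p.V1 == set(range(1, 7))
        assert not (p.V0 & p.V1)

    def test_rejects_bad_values(self):
        with pytest.raises(InputError):
            StrategyProfile((0, 2))
        with pytest.raises(InputError):
            StrategyProfile(())

    def test_flip(self):
        p = StrategyProfile((1, 0, 0))
        assert p.flipped().strategies == (0, 1, 1)


class TestLabeledGraph:
    def test_normalizes_and_validates(self):
        g = LabeledGraph.from_edges(3, [(2, 1), (2, 3)])
        assert g.edges == {(1, 2), (2, 3)}
        assert g.neighbors(2) == {1, 3}
        assert g.degree(1) == 1
        with pytest.raises(InputError):
            LabeledGraph.from_edges(3, [(1, 1)])
        with pytest.raises(DomainError):
            LabeledGraph.from_edges(3, [(1, 4)])

    def test_mask_round_trip(self):
        for mask in range(1 << 6):
            g = LabeledGraph.from_mask(4, mask)
            assert g.to_mask() == mask

    def test_toggle(self):
        g = LabeledGraph(3)
        g2 = g.with_toggled(1, 2)
        assert g2.edges == {(1, 2)}
        assert g2.with_toggled(2, 1).edges == frozenset()

    def test_vertex_pairs_order(self):
        assert vertex_pairs(4) == [(1, 2), (1, 3), (1, 4), (2, 3), (2, 4), (3, 4)]


class TestGameSpec:
    def test_cost_required_for_best_shot(self):
        with pytest.raises(InputError):
            GameSpec(Game.BEST_SHOT)
        with pytest.raises(DomainError):
            GameSpec(Game.BEST_SHOT, 1.0)
        with pytest.raises(InputError):
            GameSpec(Game.MAJORITY, 0.5)
        assert GameSpec(Game.BEST_SHOT, 0.3).cost == 0.3


class TestNeighborSplit:
    def test_direct_count(self, six_player_profile):
        g = LabeledGraph.from_edges(6, [(1, 2), (1, 3)])
        split = neighbor_split(g, six_player_profile, 1)
        assert (split.k0, split.k1) == (1, 1)

    def test_empty_graph(self):
        g = LabeledGraph(4)
        p = StrategyProfile((1, 1, 0, 0))
        for v in range(1, 5):
            split = neighbor_split(g, p, v)
            assert (split.k0, split.k1) == (0, 0)

    def test_complete_graph(self):
        g = LabeledGraph.from_edges(4, [(i, j) for i in range(1, 4)
                                        for j in range(i + 1, 5)])
        p = StrategyProfile((1, 1, 0, 0))
        split = neighbor_split(g, p, 1)
        assert (split.k0, split.k1) == (2, 1)

    def test_errors(self):
        g = LabeledGraph(3)
        p = StrategyProfile((0, 0, 0))
        with pytest.raises(DomainError):
            neighbor_split(g, p, 4)
        with pytest.raises(InputError):
            neighbor_split(g, StrategyProfile((0, 0)), 1)


class TestBestShotPayoff:
    def test_contributor(self):
        g = LabeledGraph(2)
        p = StrategyProfile((1, 0))
        spec = GameSpec(Game.BEST_SHOT, 0.3)
        assert best_shot_payoff(g, p, 1, spec) == pytest.approx(0.7)

    def test_covered_free_rider(self):
        g = LabeledGraph.from_edges(2, [(1, 2)])
        p = StrategyProfile((1, 0))
        spec = GameSpec(Game.BEST_SHOT, 0.3)
        assert best_shot_payoff(g, p, 2, spec) == 1.0

    def test_uncovered_free_rider(self):
        g = LabeledGraph(2)
        p = StrategyProfile((1, 0))
        spec = GameSpec(Game.BEST_SHOT, 0.3)
        assert best_shot_payoff(g, p, 2, spec) == 0.0

    def test_undefined_for_other_games(self):
        g = LabeledGraph(2)
        p = StrategyProfile((1, 0))
        with pytest.raises(UnsupportedGameError):
            best_shot_payoff(g, p, 1, GameSpec(Game.MAJORITY))


class TestVertexSatisfaction:
    def test_majority_strict_win(self):
        # vertex 1 plays 1 with neighbors split k0=1, k1=2
        g = LabeledGraph.from_edges(4, [(1, 2), (1, 3), (1, 4)])
        p = StrategyProfile((1, 1, 1, 0))
        assert is_vertex_satisfied(g, p, 1, Game.MAJORITY)

    @pytest.mark.parametrize("strategy", [0, 1])
    def test_majority_tie_fails(self, strategy):
        g = LabeledGraph.from_edges(3, [(1, 2), (1, 3)])
        p = StrategyProfile((strategy, 0, 1))
        assert not is_vertex_satisfied(g, p, 1, Game.MAJORITY)

    @pytest.mark.parametrize("strategy", [0, 1])
    def test_minority_tie_fails(self, strategy):
        g = LabeledGraph.from_edges(3, [(1, 2), (1, 3)])
        p = StrategyProfile((strategy, 0, 1))
        assert not is_vertex_satisfied(g, p, 1, Game.MINORITY)

    def test_isolated_lone_deviant_vacuous(self):
        # lone strategy-1 vertex among strategy-0 players must be isolated
        g = LabeledGraph.from_edges(4, [(2, 3), (3, 4), (2, 4)])
        p = StrategyProfile((1, 0, 0, 0))
        assert is_vertex_satisfied(g, p, 1, Game.MAJORITY)

    @pytest.mark.parametrize(
        "rule,expected",
        [
            (IsolatedRule.FEASIBILITY_VACUOUS, False),  # another 0-player exists
            (IsolatedRule.ACCEPT_ALL, True),
            (IsolatedRule.REJECT_ALL, False),
        ],
    )
    def test_isolated_rules(self, rule, expected):
        g = LabeledGraph(3)
        p = StrategyProfile((0, 0, 1))
        policy = EquilibriumPolicy(rule)
        assert is_vertex_satisfied(g, p, 1, Game.MAJORITY, policy) is expected

    def test_best_shot_isolated_must_contribute(self):
        g = LabeledGraph(2)
        p = StrategyProfile((1, 0))
        assert is_vertex_satisfied(g, p, 1, Game.BEST_SHOT)
        assert not is_vertex_satisfied(g, p, 2, Game.BEST_SHOT)


class TestCheckAcceptable:
    def test_best_shot_star(self):
        g = LabeledGraph.from_edges(3, [(1, 2), (1, 3)])
        p = StrategyProfile((1, 0, 0))
        report = check_acceptable(g, p, Game.BEST_SHOT)
        assert report.acceptable
        assert report.violators == frozenset()

    def test_best_shot_edge_inside_v1(self):
        g = LabeledGraph.from_edges(4, [(1, 2), (1, 3), (2, 3), (1, 4), (2, 4)])
        p = StrategyProfile((1, 1, 0, 0))
        report = check_acceptable(g, p, Game.BEST_SHOT)
        assert not report.acceptable
        assert {1, 2} <= report.violators

    def test_majority_all_zero_path(self):
        g = LabeledGraph.from_edges(3, [(1, 2), (2, 3)])
        p = StrategyProfile((0, 0, 0))
        assert check_acceptable(g, p, Game.MAJORITY).acceptable

    def test_size_mismatch(self):
        with pytest.raises(InputError):
            check_acceptable(LabeledGraph(3), StrategyProfile((0, 0)), Game.MAJORITY)

    def test_report_has_all_splits(self, six_player_profile):
        g = LabeledGraph.from_edges(6, [(1, 2), (3, 4)])
        report = check_acceptable(g, six_player_profile, Game.MINORITY)
        assert set(report.splits) == set(range(1, 7))


# ---------------------------------------------------------------------------
# properties

small_case = st.integers(2, 5).flatmap(
    lambda n: st.tuples(
        st.just(n),
        st.integers(0, (1 << (n * (n - 1) // 2)) - 1),
        st.lists(st.integers(0, 1), min_size=n, max_size=n),
    )
)


@settings(max_examples=200, deadline=None)
@given(small_case)
def test_agrees_with_oracle(case):
    n, mask, strategies = case
    g = LabeledGraph.from_mask(n, mask)
    p = StrategyProfile(tuple(strategies))
    for game in Game:
        for rule in IsolatedRule:
            got = check_acceptable(g, p, game, EquilibriumPolicy(rule)).acceptable
            want = oracle_acceptable(n, g.edges, p.strategies, game, rule.value)
            assert got == want


@settings(max_examples=100, deadline=None)
@given(small_case)
def test_mask_checker_matches_check_acceptable(case):
    n, mask, strategies = case
    p = StrategyProfile(tuple(strategies))
    for game in Game:
        check = make_mask_checker(p, game)
        assert check(mask) == check_acceptable(
            LabeledGraph.from_mask(n, mask), p, game
        ).acceptable


@settings(max_examples=100, deadline=None)
@given(small_case, st.sampled_from([0.1, 0.5, 0.9]))
def test_best_shot_verdict_independent_of_cost(case, cost):
    n, mask, strategies = case
    g = LabeledGraph.from_mask(n, mask)
    p = StrategyProfile(tuple(strategies))
    baseline = check_acceptable(g, p, Game.BEST_SHOT).acceptable
    spec = GameSpec(Game.BEST_SHOT, cost)
    assert check_acceptable(g, p, spec).acceptable == baseline


@settings(max_examples=100, deadline=None)
@given(small_case, st.sampled_from([Game.MAJORITY, Game.MINORITY]))
def test_strategy_flip_symmetry(case, game):
    n, mask, strategies = case
    g = LabeledGraph.from_mask(n, mask)
    p = StrategyProfile(tuple(strategies))
    assert (
        check_acceptable(g, p, game).acceptable
        == check_acceptable(g, p.flipped(), game).acceptable
    )


@settings(max_examples=100, deadline=None)
@given(small_case)
def test_same_strategy_edge_never_breaks_majority(case):
    n, mask, strategies = case
    g = LabeledGraph.from_mask(n, mask)
    p = StrategyProfile(tuple(strategies))
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if g.has_edge(i, j) or p.strategy(i) != p.strategy(j):
                continue
            g2 = g.with_toggled(i, j)
            for v in (i, j):
                if is_vertex_satisfied(g, p, v, Game.MAJORITY):
                    assert is_vertex_satisfied(g2, p, v, Game.MAJORITY)


@settings(max_examples=100, deadline=None)
@given(small_case)
def test_opposite_strategy_edge_never_breaks_minority(case):
    n, mask, strategies = case
    g = LabeledGraph.from_mask(n, mask)
    p = StrategyProfile(tuple(strategies))
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if g.has_edge(i, j) or p.strategy(i) == p.strategy(j):
                continue
            g2 = g.with_toggled(i, j)
            for v in (i, j):
                if is_vertex_satisfied(g, p, v, Game.MINORITY):
                    assert is_vertex_satisfied(g2, p, v, Game.MINORITY)
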