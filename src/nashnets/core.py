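"""Profiles, labeled graphs, game rules and acceptability predicates.

A *profile* assigns every player a pure strategy in {0, 1}.  A network is
*acceptable* for a (profile, game) pair when the profile is a Nash
equilibrium of that game played on the network, i.e. every vertex's
best-response condition holds simultaneously.

Player ids are 1-based throughout.  Edges are unordered pairs stored with
the smaller id first.  Vertices are labeled: two isomorphic graphs with
different edge sets are distinct objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

from .errors import DomainError, InputError, UnsupportedGameError

__all__ = [
    "Game",
    "IsolatedRule",
    "StrategyProfile",
    "LabeledGraph",
    "GameSpec",
    "EquilibriumPolicy",
    "NeighborSplit",
    "AcceptabilityReport",
    "DEFAULT_POLICY",
    "neighbor_split",
    "best_shot_payoff",
    "is_vertex_satisfied",
    "check_acceptable",
]


class Game(str, Enum):
    """The three supported binary-strategy network games."""

    MAJORITY = "majority"
    MINORITY = "minority"
    BEST_SHOT = "best-shot"


class IsolatedRule(str, Enum):
    """Convention for degree-0 vertices in the majority/minority games.

    The strict-inequality best-response conditions are undefined on an
    empty neighborhood.  ``FEASIBILITY_VACUOUS`` (the default) accepts an
    isolated vertex exactly when no wiring could ever satisfy its
    condition under the given profile: for the majority game, when no
    *other* vertex shares its strategy; for the minority game, when no
    vertex holds the opposite strategy.  ``ACCEPT_ALL``/``REJECT_ALL``
    are provided for sensitivity analysis.
    """

    FEASIBILITY_VACUOUS = "feasibility-vacuous"
    ACCEPT_ALL = "accept-all"
    REJECT_ALL = "reject-all"


@dataclass(frozen=True)
class StrategyProfile:
    """An assumed equilibrium: per-player strategies in {0, 1}.

    Parameters
    ----------
    strategies
        Ordered strategy values; position ``i`` (0-based) is player
        ``i + 1``.
    """

    strategies: tuple[int, ...]

    def __post_init__(self) -> None:
        strategies = tuple(int(s) for s in self.strategies)
        if not strategies:
            raise InputError("profile must have at least one player")
        if any(s not in (0, 1) for s in strategies):
            raise InputError(f"strategies must be 0 or 1, got {strategies!r}")
        object.__setattr__(self, "strategies", strategies)

    @property
    def n(self) -> int:
        return len(self.strategies)

    @property
    def n0(self) -> int:
        return self.n - self.n1

    @property
    def n1(self) -> int:
        return sum(self.strategies)

    @property
    def V0(self) -> frozenset[int]:
        return frozenset(i + 1 for i, s in enumerate(self.strategies) if s == 0)

    @property
    def V1(self) -> frozenset[int]:
        return frozenset(i + 1 for i, s in enumerate(self.strategies) if s == 1)

    def strategy(self, vertex: int) -> int:
        """Strategy of player ``vertex`` (1-based)."""
        _check_vertex(vertex, self.n)
        return self.strategies[vertex - 1]

    def flipped(self) -> "StrategyProfile":
        """The profile with every strategy exchanged (0 <-> 1)."""
        return StrategyProfile(tuple(1 - s for s in self.strategies))


def _normalize_edge(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class LabeledGraph:
    """A simple undirected graph on labeled vertices 1..n."""

    n: int
    edges: frozenset[tuple[int, int]] = frozenset()

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InputError(f"need at least one vertex, got n={self.n}")
        norm = set()
        for i, j in self.edges:
            if i == j:
                raise InputError(f"self-loop on vertex {i}")
            _check_vertex(i, self.n)
            _check_vertex(j, self.n)
            norm.add(_normalize_edge(i, j))
        object.__setattr__(self, "edges", frozenset(norm))

    @classmethod
    def from_edges(cls, n: int, edges: Iterable[tuple[int, int]]) -> "LabeledGraph":
        return cls(n, frozenset(tuple(e) for e in edges))

    @classmethod
    def from_mask(cls, n: int, mask: int) -> "LabeledGraph":
        """Build from an edge bitmask over :func:`vertex_pairs` order."""
        pairs = vertex_pairs(n)
        if not 0 <= mask < (1 << len(pairs)):
            raise DomainError(f"mask {mask} out of range for n={n}")
        return cls(n, frozenset(p for b, p in enumerate(pairs) if mask >> b & 1))

    def to_mask(self) -> int:
        """Edge bitmask over :func:`vertex_pairs` order."""
        index = {p: b for b, p in enumerate(vertex_pairs(self.n))}
        mask = 0
        for e in self.edges:
            mask |= 1 << index[e]
        return mask

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    @property
    def max_edges(self) -> int:
        return self.n * (self.n - 1) // 2

    def neighbors(self, vertex: int) -> frozenset[int]:
        _check_vertex(vertex, self.n)
        return frozenset(
            j if i == vertex else i for i, j in self.edges if vertex in (i, j)
        )

    def degree(self, vertex: int) -> int:
        return len(self.neighbors(vertex))

    def has_edge(self, i: int, j: int) -> bool:
        return _normalize_edge(i, j) in self.edges

    def with_toggled(self, i: int, j: int) -> "LabeledGraph":
        """Copy with edge (i, j) added if absent, removed if present."""
        e = _normalize_edge(i, j)
        if e in self.edges:
            return LabeledGraph(self.n, self.edges - {e})
        return LabeledGraph(self.n, self.edges | {e})

    def adjacency(self) -> dict[int, set[int]]:
        """Neighbor sets for all vertices (computed once per call)."""
        adj: dict[int, set[int]] = {v: set() for v in range(1, self.n + 1)}
        for i, j in self.edges:
            adj[i].add(j)
            adj[j].add(i)
        return adj


def vertex_pairs(n: int) -> list[tuple[int, int]]:
    """All unordered vertex pairs in lexicographic order.

    This fixed order -- (1,2), (1,3), ..., (1,n), (2,3), ..., (n-1,n) --
    defines the canonical bitmask encoding of graphs used everywhere in
    the package (bit ``b`` set <=> pair ``b`` is an edge).
    """
    return [(i, j) for i in range(1, n) for j in range(i + 1, n + 1)]


@dataclass(frozen=True)
class GameSpec:
    """Game selector plus the best-shot contribution cost ``c``.

    ``cost`` is required (and must lie in the open interval (0, 1)) only
    for the best-shot game, and only its payoff uses it: acceptability
    verdicts never depend on ``cost``.
    """

    game: Game
    cost: float | None = None

    def __post_init__(self) -> None:
        game = Game(self.game)
        object.__setattr__(self, "game", game)
        if game is Game.BEST_SHOT:
            if self.cost is None:
                raise InputError("best-shot game requires a cost c")
            if not 0.0 < float(self.cost) < 1.0:
                raise DomainError(f"best-shot cost must be in (0,1), got {self.cost}")
        elif self.cost is not None:
            raise InputError(f"game {game.value} takes no cost parameter")


@dataclass(frozen=True)
class EquilibriumPolicy:
    """Fixed conventions resolving cases the game rules leave open.

    Tie handling is not configurable: an exactly even same/opposite
    neighbor split never satisfies the strict majority or minority
    inequalities.
    """

    isolated_rule: IsolatedRule = IsolatedRule.FEASIBILITY_VACUOUS

    def __post_init__(self) -> None:
        object.__setattr__(self, "isolated_rule", IsolatedRule(self.isolated_rule))


DEFAULT_POLICY = EquilibriumPolicy()


@dataclass(frozen=True)
class NeighborSplit:
    """Counts of a vertex's neighbors by their strategy class."""

    k0: int
    k1: int

    @property
    def degree(self) -> int:
        return self.k0 + self.k1


@dataclass(frozen=True)
class AcceptabilityReport:
    """Verdict plus per-vertex diagnostics for a (graph, profile, game)."""

    acceptable: bool
    violators: frozenset[int]
    splits: Mapping[int, NeighborSplit]

    def __post_init__(self) -> None:
        if self.acceptable != (not self.violators):
            raise InputError("acceptable flag inconsistent with violator set")


def _check_vertex(vertex: int, n: int) -> None:
    if not 1 <= vertex <= n:
        raise DomainError(f"vertex id {vertex} out of range 1..{n}")


def _check_sizes(graph: LabeledGraph, profile: StrategyProfile) -> None:
    if graph.n != profile.n:
        raise InputError(
            f"graph has {graph.n} vertices but profile has {profile.n} players"
        )


def neighbor_split(
    graph: LabeledGraph, profile: StrategyProfile, vertex: int
) -> NeighborSplit:
    """Count ``vertex``'s neighbors carrying strategy 0 and strategy 1."""
    _check_sizes(graph, profile)
    _check_vertex(vertex, graph.n)
    k0 = k1 = 0
    for u in graph.neighbors(vertex):
        if profile.strategies[u - 1] == 1:
            k1 += 1
        else:
            k0 += 1
    return NeighborSplit(k0=k0, k1=k1)


def best_shot_payoff(
    graph: LabeledGraph, profile: StrategyProfile, vertex: int, spec: GameSpec
) -> float:
    """Best-shot payoff: 1-c for a contributor; 1 for a covered
    free-rider; 0 for an uncovered free-rider."""
    if spec.game is not Game.BEST_SHOT:
        raise UnsupportedGameError(
            f"no cardinal payoff defined for {spec.game.value}; "
            "only the ordinal best-response predicate is available"
        )
    _check_sizes(graph, profile)
    _check_vertex(vertex, graph.n)
    if profile.strategy(vertex) == 1:
        return 1.0 - float(spec.cost)  # type: ignore[arg-type]
    split = neighbor_split(graph, profile, vertex)
    return 1.0 if split.k1 >= 1 else 0.0


def _isolated_ok(
    strategy: int, profile: StrategyProfile, game: Game, policy: EquilibriumPolicy
) -> bool:
    rule = policy.isolated_rule
    if rule is IsolatedRule.ACCEPT_ALL:
        return True
    if rule is IsolatedRule.REJECT_ALL:
        return False
    # feasibility-vacuous: accept iff the condition is unsatisfiable by
    # any wiring under this profile
    if game is Game.MAJORITY:
        # needs a same-strategy neighbor, so some OTHER vertex must share
        # the strategy
        return (profile.n1 == 1) if strategy == 1 else (profile.n0 == 1)
    # minority: needs an opposite-strategy neighbor
    return (profile.n0 == 0) if strategy == 1 else (profile.n1 == 0)


def _split_ok(
    strategy: int,
    split: NeighborSplit,
    profile: StrategyProfile,
    game: Game,
    policy: EquilibriumPolicy,
) -> bool:
    if game is Game.BEST_SHOT:
        return split.k1 == 0 if strategy == 1 else split.k1 >= 1
    if split.degree == 0:
        return _isolated_ok(strategy, profile, game, policy)
    same, opp = (split.k1, split.k0) if strategy == 1 else (split.k0, split.k1)
    return same > opp if game is Game.MAJORITY else same < opp


def is_vertex_satisfied(
    graph: LabeledGraph,
    profile: StrategyProfile,
    vertex: int,
    spec: GameSpec | Game,
    policy: EquilibriumPolicy = DEFAULT_POLICY,
) -> bool:
    """Whether ``vertex`` is playing a best response on ``graph``.

    Majority: a non-isolated vertex needs strictly more same-strategy
    than opposite-strategy neighbors.  Minority: strictly fewer.
    Best-shot: a contributor must have no contributing neighbor; a
    free-rider must have at least one.  Isolated majority/minority
    vertices are resolved by ``policy.isolated_rule``.
    """
    game = spec.game if isinstance(spec, GameSpec) else Game(spec)
    split = neighbor_split(graph, profile, vertex)
    return _split_ok(profile.strategy(vertex), split, profile, game, policy)


def check_acceptable(
    graph: LabeledGraph,
    profile: StrategyProfile,
    spec: GameSpec | Game,
    policy: EquilibriumPolicy = DEFAULT_POLICY,
) -> AcceptabilityReport:
    """Decide whether ``graph`` realizes the assumed equilibrium.

    The graph is acceptable iff every vertex simultaneously plays a best
    response; a single failing vertex rejects the whole network.
    """
    _check_sizes(graph, profile)
    game = spec.game if isinstance(spec, GameSpec) else Game(spec)
    adj = graph.adjacency()
    strategies = profile.strategies
    splits: dict[int, NeighborSplit] = {}
    violators: set[int] = set()
    for v in range(1, graph.n + 1):
        k1 = sum(strategies[u - 1] for u in adj[v])
        split = NeighborSplit(k0=len(adj[v]) - k1, k1=k1)
        splits[v] = split
        if not _split_ok(strategies[v - 1], split, profile, game, policy):
            violators.add(v)
    return AcceptabilityReport(
        acceptable=not violators, violators=frozenset(violators), splits=splits
    )


def make_mask_checker(
    profile: StrategyProfile,
    spec: GameSpec | Game,
    policy: EquilibriumPolicy = DEFAULT_POLICY,
):
    """Compile a fast acceptability predicate over edge bitmasks.

    Returns ``check(mask) -> bool`` agreeing with :func:`check_acceptable`
    on ``LabeledGraph.from_mask(n, mask)``.  Used by the enumeration scan
    and the edge-toggle walk, where millions of graphs are tested.
    """
    game = spec.game if isinstance(spec, GameSpec) else Game(spec)
    n = profile.n
    strategies = profile.strategies
    pairs = vertex_pairs(n)
    m0 = [0] * (n + 1)  # bits of incident pairs whose far end plays 0
    m1 = [0] * (n + 1)
    for b, (i, j) in enumerate(pairs):
        if strategies[j - 1] == 1:
            m1[i] |= 1 << b
        else:
            m0[i] |= 1 << b
        if strategies[i - 1] == 1:
            m1[j] |= 1 << b
        else:
            m0[j] |= 1 << b
    iso_ok = [
        _isolated_ok(strategies[v - 1], profile, game, policy)
        for v in range(1, n + 1)
    ]
    verts = range(1, n + 1)

    if game is Game.BEST_SHOT:

        def check(mask: int) -> bool:
            for v in verts:
                covered = mask & m1[v]
                if strategies[v - 1] == 1:
                    if covered:
                        return False
                elif not covered:
                    return False
            return True

        return check

    majority = game is Game.MAJORITY

    def check(mask: int) -> bool:  # noqa: F811 - deliberate variant
        for v in verts:
            k0 = (mask & m0[v]).bit_count()
            k1 = (mask & m1[v]).bit_count()
            if k0 == 0 and k1 == 0:
                if not iso_ok[v - 1]:
                    return False
                continue
            same, opp = (k1, k0) if strategies[v - 1] == 1 else (k0, k1)
            if majority:
                if same <= opp:
                    return False
            elif same >= opp:
                return False
        return True

    return check
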