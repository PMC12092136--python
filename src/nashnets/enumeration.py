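"""Exhaustive and structure-aware generation of acceptable networks.

The space of labeled simple graphs on n vertices is indexed by edge
bitmasks over :func:`nashnets.core.vertex_pairs` order, giving a fixed,
reproducible enumeration sequence (mask 0 = empty graph, all-ones mask =
complete graph).  Brute force is guarded by a configurable ceiling since
the space has size 2^(n(n-1)/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterator

from .core import (
    DEFAULT_POLICY,
    EquilibriumPolicy,
    Game,
    GameSpec,
    LabeledGraph,
    StrategyProfile,
    make_mask_checker,
    vertex_pairs,
)
from .counting import CountResult, count_acceptable, count_best_shot
from .errors import DomainError, ResourceLimitError

__all__ = [
    "BRUTE_FORCE_CEILING",
    "EdgeHistogram",
    "graph_space",
    "iter_acceptable",
    "enumerate_acceptable",
    "structured_enumerate_best_shot",
    "composition_sweep",
]

logger = logging.getLogger(__name__)

#: Default largest n for which the full 2^(n(n-1)/2) scan is permitted.
BRUTE_FORCE_CEILING = 7

_PROGRESS_EVERY = 100_000


@dataclass
class EdgeHistogram:
    """Acceptable-network counts keyed by edge count (the N1 series)."""

    n: int
    counts: dict[int, int] = field(default_factory=dict)

    def add(self, edge_count: int) -> None:
        self.counts[edge_count] = self.counts.get(edge_count, 0) + 1

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def max_edges(self) -> int:
        return self.n * (self.n - 1) // 2

    def as_series(self) -> list[tuple[int, int]]:
        """(edges, count) rows over the full range 0..max_edges."""
        return [(e, self.counts.get(e, 0)) for e in range(self.max_edges + 1)]

    def support(self) -> list[int]:
        return sorted(e for e, c in self.counts.items() if c > 0)


def _check_ceiling(n: int, ceiling: int | None) -> None:
    if n < 1:
        raise DomainError(f"need n >= 1, got {n}")
    if ceiling is not None and n > ceiling:
        raise ResourceLimitError(
            f"n={n} exceeds the brute-force ceiling of {ceiling} "
            f"(2^{n * (n - 1) // 2} graphs); raise the ceiling explicitly "
            "to override"
        )


def graph_space(
    n: int, ceiling: int | None = BRUTE_FORCE_CEILING
) -> Iterator[LabeledGraph]:
    """Yield every labeled simple graph on n vertices exactly once.

    Order is the canonical bitmask order: mask 0 (empty graph) first,
    then masks in increasing numeric order up to the complete graph.
    """
    _check_ceiling(n, ceiling)
    pairs = vertex_pairs(n)
    for mask in range(1 << len(pairs)):
        yield LabeledGraph(
            n, frozenset(p for b, p in enumerate(pairs) if mask >> b & 1)
        )


def iter_acceptable(
    profile: StrategyProfile,
    spec: GameSpec | Game,
    policy: EquilibriumPolicy = DEFAULT_POLICY,
    ceiling: int | None = BRUTE_FORCE_CEILING,
) -> Iterator[LabeledGraph]:
    """Stream the acceptable graphs for (profile, game, policy) in
    canonical bitmask order, by scanning the full space."""
    n = profile.n
    _check_ceiling(n, ceiling)
    check = make_mask_checker(profile, spec, policy)
    pairs = vertex_pairs(n)
    for mask in range(1 << len(pairs)):
        if check(mask):
            yield LabeledGraph(
                n, frozenset(p for b, p in enumerate(pairs) if mask >> b & 1)
            )


def enumerate_acceptable(
    profile: StrategyProfile,
    spec: GameSpec | Game,
    policy: EquilibriumPolicy = DEFAULT_POLICY,
    keep_graphs: bool = True,
    ceiling: int | None = BRUTE_FORCE_CEILING,
) -> tuple[list[LabeledGraph] | None, EdgeHistogram]:
    """Scan the full graph space; return the acceptable graphs (when
    ``keep_graphs``) and their edge-count histogram.

    With ``keep_graphs=False`` only the histogram is built, in constant
    memory per graph.
    """
    n = profile.n
    _check_ceiling(n, ceiling)
    check = make_mask_checker(profile, spec, policy)
    hist = EdgeHistogram(n)
    graphs: list[LabeledGraph] | None = [] if keep_graphs else None
    pairs = vertex_pairs(n)
    space = 1 << len(pairs)
    for mask in range(space):
        if mask and mask % _PROGRESS_EVERY == 0:
            logger.info("scanned %d/%d graphs", mask, space)
        if check(mask):
            hist.add(mask.bit_count())
            if graphs is not None:
                graphs.append(
                    LabeledGraph(
                        n, frozenset(p for b, p in enumerate(pairs) if mask >> b & 1)
                    )
                )
    return graphs, hist


def structured_enumerate_best_shot(
    profile: StrategyProfile,
    max_graphs: int | None = 1 << 22,
) -> Iterator[LabeledGraph]:
    """Generate acceptable best-shot networks without scanning the space.

    An acceptable network decomposes into three independent blocks: an
    empty block inside the contributor set V1, an unrestricted block
    inside V0, and a cross block in which every V0 vertex picks a
    non-empty subset of V1 neighbors.  The generator takes the product
    of the three blocks; its output equals brute-force enumeration.
    """
    v0 = sorted(profile.V0)
    v1 = sorted(profile.V1)
    n = profile.n
    expected = count_best_shot(profile.n0, profile.n1).count
    if max_graphs is not None and expected > max_graphs:
        raise ResourceLimitError(
            f"{expected} acceptable best-shot graphs exceed the output "
            f"guard of {max_graphs}; pass max_graphs=None to override"
        )
    if expected == 0:
        return
    v0_pairs = [(a, b) for i, a in enumerate(v0) for b in v0[i + 1:]]
    # non-empty V1-neighborhood choices for one V0 vertex, as bitmasks
    v1_choices = list(range(1, 1 << len(v1))) or [0]
    free_block = range(1 << len(v0_pairs))
    for v0_mask in free_block:
        base = frozenset(
            p for b, p in enumerate(v0_pairs) if v0_mask >> b & 1
        )
        for cross in product(v1_choices, repeat=len(v0)):
            edges = set(base)
            for a, choice in zip(v0, cross):
                for b_idx, b in enumerate(v1):
                    if choice >> b_idx & 1:
                        edges.add((a, b) if a < b else (b, a))
            yield LabeledGraph(n, frozenset(edges))


def composition_sweep(
    n: int,
    spec: GameSpec | Game,
    policy: EquilibriumPolicy = DEFAULT_POLICY,
    mode: str = "auto",
    ceiling: int | None = BRUTE_FORCE_CEILING,
) -> dict[int, CountResult]:
    """Acceptable-network count for every composition n1 = 0..n.

    Closed forms are used where available, exhaustive enumeration
    elsewhere (``mode`` as in the counting module).
    """
    if n < 1:
        raise DomainError(f"need n >= 1, got {n}")
    game = spec.game if isinstance(spec, GameSpec) else Game(spec)
    result: dict[int, CountResult] = {}
    for n1 in range(n + 1):
        result[n1] = count_acceptable(game, n - n1, n1, mode=mode, policy=policy)
    return result
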