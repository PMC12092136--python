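"""Occurrence-probability experiment over the graph space.

From every possible network we run a random edge add/remove walk and
record the first acceptable network reached.  Aggregating first-hit edge
counts over R independent realizations gives the N2 histogram, compared
against the N1 histogram of acceptable networks to estimate how
occurrence probability varies with density.

Two move rules are provided.  ``"add-remove"`` (the default) first
draws the operation -- add or remove, each with probability 1/2 -- and
then a uniformly random vertex pair eligible for it; a step with no
eligible pair (remove at the empty graph, add at the complete graph) is
a no-op.  ``"toggle"`` flips one uniformly random vertex pair per step.
Both chains are irreducible over the graph space, so a walk is absorbed
with probability one whenever the acceptable set is non-empty;
``max_steps`` is purely a guard against misconfiguration.  Only the
add-remove rule reproduces the qualitative density trend (occurrence
probability rising with edge count); under the toggle rule the
first-hit distribution over any block of edges untouched by the
acceptability conditions stays uniform, flattening the ratio series.

By default the experiment requires every walk to make at least one
move, even from an acceptable start (``absorb_start=False``).  With
``absorb_start=True`` acceptable starts count as their own first hit:
then every edge-count bin's N2/N1 ratio is at least R while bins whose
entire graph layer is acceptable are pinned at exactly R (no walk can
reach them from outside without being absorbed earlier), so a rising
ratio trend is impossible whenever dense layers are fully acceptable --
as in the all-same-strategy majority scenarios.

Seeding: one root seed spawns an independent sub-stream per
(start graph, realization), so results are reproducible and independent
of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .core import (
    DEFAULT_POLICY,
    EquilibriumPolicy,
    Game,
    GameSpec,
    LabeledGraph,
    StrategyProfile,
    make_mask_checker,
)
from .enumeration import (
    BRUTE_FORCE_CEILING,
    EdgeHistogram,
    enumerate_acceptable,
)
from .errors import DomainError, NonConvergenceError, ResourceLimitError

__all__ = [
    "DEFAULT_SCALES",
    "WalkConfig",
    "WalkResult",
    "ExperimentResult",
    "DensitySummary",
    "random_walk",
    "occurrence_experiment",
    "density_summary",
]

logger = logging.getLogger(__name__)

#: Display scaling of the N2/N1 ratio series, by game.
DEFAULT_SCALES: dict[Game, float] = {
    Game.MAJORITY: 50.0,
    Game.BEST_SHOT: 0.5,
    Game.MINORITY: 0.5,
}

_WALK_PROGRESS_EVERY = 1_000


_MOVE_RULES = ("add-remove", "toggle")


@dataclass(frozen=True)
class WalkConfig:
    """Parameters of the occurrence experiment."""

    realizations: int = 100
    seed: int = 0
    max_steps: int = 1_000_000
    scale: float | None = None  # None -> per-game default
    move_rule: str = "add-remove"
    absorb_start: bool = False

    def __post_init__(self) -> None:
        if self.realizations < 1:
            raise DomainError("realizations must be >= 1")
        if self.max_steps < 1:
            raise DomainError("max_steps must be >= 1")
        if self.move_rule not in _MOVE_RULES:
            raise DomainError(f"move_rule must be one of {_MOVE_RULES}")


@dataclass(frozen=True)
class WalkResult:
    final_graph: LabeledGraph
    steps: int

    @property
    def final_edge_count(self) -> int:
        return self.final_graph.edge_count


@dataclass(frozen=True)
class DensitySummary:
    """Moments of an edge-count histogram plus a unimodality flag."""

    mean: float
    variance: float
    skewness: float
    unimodal: bool


@dataclass
class ExperimentResult:
    """N1/N2 histograms, scaled ratio series and density trend."""

    profile: StrategyProfile
    game: Game
    realizations: int
    seed: int
    move_rule: str
    n1_hist: EdgeHistogram
    n2_hist: dict[int, int]
    scale: float
    trend: float  # Spearman rank correlation of edge count vs N2/N1

    @property
    def ratio(self) -> dict[int, float]:
        """scale * N2/N1 wherever N1 > 0."""
        return {
            e: self.scale * self.n2_hist.get(e, 0) / c
            for e, c in sorted(self.n1_hist.counts.items())
            if c > 0
        }

    @property
    def total_walks(self) -> int:
        return sum(self.n2_hist.values())

    def as_rows(self) -> list[tuple[int, int, int, float]]:
        """(edges, N1, N2, ratio) rows over 0..max_edges."""
        ratio = self.ratio
        return [
            (e, n1, self.n2_hist.get(e, 0), ratio.get(e, 0.0))
            for e, n1 in self.n1_hist.as_series()
        ]


def _step(mask: int, n_pairs: int, rng: np.random.Generator, move_rule: str) -> int:
    """One random edge move; returns the (possibly unchanged) mask."""
    if move_rule == "toggle":
        return mask ^ (1 << int(rng.integers(n_pairs)))
    adding = bool(rng.integers(2))
    present = mask.bit_count()
    n_candidates = n_pairs - present if adding else present
    if n_candidates == 0:
        return mask
    pick = int(rng.integers(n_candidates))
    for b in range(n_pairs):
        if bool(mask >> b & 1) != adding:
            if pick == 0:
                return mask ^ (1 << b)
            pick -= 1
    raise AssertionError("unreachable: candidate count mismatch")


def _walk_mask(
    start_mask: int,
    n_pairs: int,
    check,
    rng: np.random.Generator,
    max_steps: int,
    move_rule: str,
    min_steps: int,
) -> tuple[int, int]:
    """Run the absorbed walk on bitmasks; return (final mask, steps)."""
    if min_steps == 0 and check(start_mask):
        return start_mask, 0
    mask = start_mask
    for step in range(1, max_steps + 1):
        mask = _step(mask, n_pairs, rng, move_rule)
        if check(mask):
            return mask, step
    raise NonConvergenceError(max_steps, start_mask=start_mask)


def random_walk(
    start: LabeledGraph,
    profile: StrategyProfile,
    spec: GameSpec | Game,
    policy: EquilibriumPolicy = DEFAULT_POLICY,
    max_steps: int = 1_000_000,
    rng: np.random.Generator | None = None,
    move_rule: str = "add-remove",
    min_steps: int = 0,
) -> WalkResult:
    """Randomly add/remove edges until the graph is acceptable.

    A start that is already acceptable is returned with ``steps = 0``
    (unless ``min_steps`` forces at least one move).  Raises
    :class:`NonConvergenceError` if ``max_steps`` elapse without
    absorption (possible only for an empty acceptable set or a far too
    small guard).
    """
    if rng is None:
        rng = np.random.default_rng()
    if move_rule not in _MOVE_RULES:
        raise DomainError(f"move_rule must be one of {_MOVE_RULES}")
    check = make_mask_checker(profile, spec, policy)
    n = profile.n
    mask, steps = _walk_mask(
        start.to_mask(), n * (n - 1) // 2, check, rng, max_steps, move_rule,
        min_steps,
    )
    final = start if steps == 0 else LabeledGraph.from_mask(n, mask)
    return WalkResult(final_graph=final, steps=steps)


def occurrence_experiment(
    profile: StrategyProfile,
    spec: GameSpec | Game,
    policy: EquilibriumPolicy = DEFAULT_POLICY,
    config: WalkConfig = WalkConfig(),
    ceiling: int | None = BRUTE_FORCE_CEILING,
) -> ExperimentResult:
    """Run the edge-toggle walk from every graph in the space, R times.

    N2 totals first-hit edge counts summed over all starts and all
    realizations, so ``sum(N2) = R * 2^(n(n-1)/2)`` exactly.
    """
    game = spec.game if isinstance(spec, GameSpec) else Game(spec)
    n = profile.n
    n_pairs = n * (n - 1) // 2
    if ceiling is not None and n > ceiling:
        raise ResourceLimitError(
            f"start space 2^{n_pairs} exceeds the ceiling n={ceiling}"
        )
    _, n1_hist = enumerate_acceptable(
        profile, spec, policy, keep_graphs=False, ceiling=ceiling
    )
    if n1_hist.total == 0:
        raise DomainError(
            "acceptable set is empty for this profile/game; no walk can be absorbed"
        )
    check = make_mask_checker(profile, spec, policy)
    space = 1 << n_pairs
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(space * config.realizations)
    min_steps = 0 if config.absorb_start else 1
    n2_hist: dict[int, int] = {}
    walk_idx = 0
    for start_mask in range(space):
        for _ in range(config.realizations):
            rng = np.random.default_rng(children[walk_idx])
            final, _steps = _walk_mask(
                start_mask, n_pairs, check, rng, config.max_steps,
                config.move_rule, min_steps,
            )
            hit = final.bit_count()
            n2_hist[hit] = n2_hist.get(hit, 0) + 1
            walk_idx += 1
            if walk_idx % _WALK_PROGRESS_EVERY == 0:
                logger.info(
                    "completed %d/%d walks", walk_idx, space * config.realizations
                )
    scale = config.scale if config.scale is not None else DEFAULT_SCALES[game]
    trend = _rank_trend(n1_hist, n2_hist)
    return ExperimentResult(
        profile=profile,
        game=game,
        realizations=config.realizations,
        seed=config.seed,
        move_rule=config.move_rule,
        n1_hist=n1_hist,
        n2_hist=n2_hist,
        scale=scale,
        trend=trend,
    )


def _rank_trend(n1_hist: EdgeHistogram, n2_hist: Mapping[int, int]) -> float:
    """Spearman rank correlation between edge count and N2/N1 over the
    support of N1.  NaN when fewer than two support points exist."""
    support = n1_hist.support()
    if len(support) < 2:
        return float("nan")
    ratios = [n2_hist.get(e, 0) / n1_hist.counts[e] for e in support]
    rho, _ = stats.spearmanr(support, ratios)
    return float(rho)


def density_summary(hist: EdgeHistogram) -> DensitySummary:
    """Weighted moments of the edge-count distribution and a unimodality
    flag (single local maximum after merging tied plateaus)."""
    if hist.total == 0:
        raise DomainError("histogram is empty")
    edges = np.array(sorted(hist.counts), dtype=float)
    weights = np.array([hist.counts[int(e)] for e in edges], dtype=float)
    w = weights / weights.sum()
    mean = float(np.sum(w * edges))
    variance = float(np.sum(w * (edges - mean) ** 2))
    if variance > 0:
        skewness = float(np.sum(w * (edges - mean) ** 3) / variance**1.5)
    else:
        skewness = 0.0
    return DensitySummary(
        mean=mean, variance=variance, skewness=skewness, unimodal=_unimodal(hist)
    )


def _unimodal(hist: EdgeHistogram) -> bool:
    lo, hi = min(hist.counts), max(hist.counts)
    series = [hist.counts.get(e, 0) for e in range(lo, hi + 1)]
    # merge tied plateaus, then require rise-then-fall
    merged = [series[0]]
    for v in series[1:]:
        if v != merged[-1]:
            merged.append(v)
    peaked = False
    for prev, cur in zip(merged, merged[1:]):
        if cur > prev and peaked:
            return False
        if cur < prev:
            peaked = True
    return True
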