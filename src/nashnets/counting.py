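"""Exact counts of acceptable labeled networks.

Closed forms exist for the best-shot game at every composition, for the
majority game when the smaller strategy class has at most two members,
and for the minority game when it has at most one.  All other
compositions have no known closed form and are routed to exhaustive
enumeration.  Everything is computed in exact integer arithmetic: the
alternating inclusion-exclusion sums cancel catastrophically in floats.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from math import comb

from .core import DEFAULT_POLICY, EquilibriumPolicy, Game, StrategyProfile
from .errors import DomainError, NoClosedFormError

__all__ = [
    "CountMethod",
    "CountResult",
    "covering_bipartite_count",
    "count_best_shot",
    "count_majority_all_same",
    "count_majority",
    "count_minority",
    "count_acceptable",
]


class CountMethod(str, Enum):
    CLOSED_FORM = "closed-form"
    THEOREM_SPECIAL_CASE = "theorem-special-case"
    ENUMERATION = "enumeration"


@dataclass(frozen=True)
class CountResult:
    game: Game
    n0: int
    n1: int
    count: int
    method: CountMethod

    def __post_init__(self) -> None:
        if self.count < 0:
            raise DomainError("counts are non-negative")

    def __int__(self) -> int:
        return self.count


def _check_nonneg(**kwargs: int) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise DomainError(f"{name} must be >= 0, got {value}")


def covering_bipartite_count(m: int, k: int) -> int:
    """Number of bipartite edge subsets between an m-set and a k-set in
    which every member of the m-set has degree >= 1.

    By inclusion-exclusion over the uncovered m-vertices this equals
    ``sum_i (-1)^i C(m,i) 2^((m-i)k)``, which telescopes to
    ``(2^k - 1)^m``; the alternating sum is evaluated explicitly and
    cross-checked against the product form.
    """
    _check_nonneg(m=m, k=k)
    total = sum((-1) ** i * comb(m, i) * 2 ** ((m - i) * k) for i in range(m + 1))
    assert total == (2**k - 1) ** m
    return total


def count_best_shot(n0: int, n1: int) -> CountResult:
    """Acceptable best-shot networks: free subgraph on the n0
    free-riders times a covering bipartite block (every free-rider gets
    at least one contributing neighbor); no edges among contributors."""
    _check_nonneg(n0=n0, n1=n1)
    count = 2 ** (n0 * (n0 - 1) // 2) * covering_bipartite_count(n0, n1)
    return CountResult(Game.BEST_SHOT, n0, n1, count, CountMethod.CLOSED_FORM)


def count_majority_all_same(n0: int) -> CountResult:
    """Labeled graphs on n0 vertices with minimum degree >= 1 -- the
    acceptable majority networks when every player holds the same
    strategy (each vertex needs at least one same-strategy neighbor)."""
    _check_nonneg(n0=n0)
    count = sum(
        (-1) ** i * comb(n0, i) * 2 ** comb(n0 - i, 2) for i in range(n0 + 1)
    )
    return CountResult(Game.MAJORITY, n0, 0, count, CountMethod.CLOSED_FORM)


def _enumerated(game: Game, n0: int, n1: int, policy: EquilibriumPolicy) -> CountResult:
    from .enumeration import enumerate_acceptable  # deferred: avoids cycle

    profile = StrategyProfile((0,) * n0 + (1,) * n1)
    _, hist = enumerate_acceptable(profile, game, policy, keep_graphs=False)
    return CountResult(game, n0, n1, hist.total, CountMethod.ENUMERATION)


def count_majority(
    n0: int,
    n1: int,
    mode: str = "auto",
    policy: EquilibriumPolicy = DEFAULT_POLICY,
) -> CountResult:
    """Acceptable majority networks at composition (n0, n1).

    The count is symmetric in (n0, n1).  When the smaller class has at
    most two members (and the larger at least two -- the collapse
    argument needs a non-degenerate majority class) it collapses to
    :func:`count_majority_all_same` of the larger class: a lone deviant
    must be isolated; a deviant pair must form a private edge.
    Otherwise no closed form is known: ``mode`` "formula" raises
    :class:`NoClosedFormError`, "auto"/"enumerate" fall back to
    exhaustive enumeration under the default policy.  At the degenerate
    one- and two-player compositions with no majority class the
    enumerated count (1: the empty graph, via the feasibility-vacuous
    isolated rule) differs from the collapse value, so those are always
    enumerated.
    """
    _check_nonneg(n0=n0, n1=n1)
    if n0 + n1 == 0:
        return CountResult(Game.MAJORITY, 0, 0, 1, CountMethod.CLOSED_FORM)
    lo, hi = min(n0, n1), max(n0, n1)
    if mode != "enumerate" and lo <= 2 and hi >= 2:
        base = count_majority_all_same(hi)
        method = (
            CountMethod.CLOSED_FORM if lo == 0 else CountMethod.THEOREM_SPECIAL_CASE
        )
        return CountResult(Game.MAJORITY, n0, n1, base.count, method)
    if mode == "formula":
        raise NoClosedFormError(Game.MAJORITY.value, n0, n1)
    return _enumerated(Game.MAJORITY, n0, n1, policy)


def count_minority(
    n0: int,
    n1: int,
    mode: str = "auto",
    policy: EquilibriumPolicy = DEFAULT_POLICY,
) -> CountResult:
    """Acceptable minority networks at composition (n0, n1).

    Symmetric in (n0, n1); exactly one acceptable network exists when
    the smaller class has at most one member (the empty graph when it is
    empty, the full star from the lone deviant otherwise) -- these
    special cases assume the default feasibility-vacuous isolated rule.
    Otherwise enumeration, as for :func:`count_majority`.
    """
    _check_nonneg(n0=n0, n1=n1)
    lo = min(n0, n1)
    if mode != "enumerate" and lo <= 1:
        method = (
            CountMethod.CLOSED_FORM if lo == 0 else CountMethod.THEOREM_SPECIAL_CASE
        )
        if policy == DEFAULT_POLICY:
            return CountResult(Game.MINORITY, n0, n1, 1, method)
    if mode == "formula":
        raise NoClosedFormError(Game.MINORITY.value, n0, n1)
    return _enumerated(Game.MINORITY, n0, n1, policy)


def count_acceptable(
    game: Game | str,
    n0: int,
    n1: int,
    mode: str = "auto",
    policy: EquilibriumPolicy = DEFAULT_POLICY,
) -> CountResult:
    """Dispatch to the per-game counting routine."""
    game = Game(game)
    if game is Game.BEST_SHOT:
        if mode == "enumerate":
            return _enumerated(game, n0, n1, policy)
        return count_best_shot(n0, n1)
    if game is Game.MAJORITY:
        return count_majority(n0, n1, mode=mode, policy=policy)
    return count_minority(n0, n1, mode=mode, policy=policy)
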