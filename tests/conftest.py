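"""Shared fixtures and an independent brute-force oracle.

The oracle re-derives acceptability straight from the game definitions
using plain sets and itertools, deliberately sharing no code with the
package, so package results are always checked through two routes.
"""

from itertools import chain, combinations

import pytest

from nashnets import Game, IsolatedRule


def powerset(items):
    items = list(items)
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))


def all_pairs(n):
    return list(combinations(range(1, n + 1), 2))


def oracle_acceptable(n, edges, strategies, game, isolated_rule="feasibility-vacuous"):
    """Direct, slow re-derivation of the acceptability verdict."""
    game = Game(game)
    nbrs = {v: set() for v in range(1, n + 1)}
    for i, j in edges:
        nbrs[i].add(j)
        nbrs[j].add(i)
    n1 = sum(strategies)
    n0 = n - n1
    for v in range(1, n + 1):
        s = strategies[v - 1]
        k1 = sum(1 for u in nbrs[v] if strategies[u - 1] == 1)
        k0 = len(nbrs[v]) - k1
        if game is Game.BEST_SHOT:
            ok = (k1 == 0) if s == 1 else (k1 >= 1)
        elif k0 == 0 and k1 == 0:
            rule = IsolatedRule(isolated_rule)
            if rule is IsolatedRule.ACCEPT_ALL:
                ok = True
            elif rule is IsolatedRule.REJECT_ALL:
                ok = False
            elif game is Game.MAJORITY:
                ok = (n0 == 1) if s == 0 else (n1 == 1)
            else:
                ok = (n1 == 0) if s == 0 else (n0 == 0)
        else:
            same, opp = (k1, k0) if s == 1 else (k0, k1)
            ok = same > opp if game is Game.MAJORITY else same < opp
        if not ok:
            return False
    return True


def oracle_count(n0, n1, game, isolated_rule="feasibility-vacuous"):
    """Brute-force count over all labeled graphs on n0+n1 vertices."""
    n = n0 + n1
    strategies = (0,) * n0 + (1,) * n1
    return sum(
        1
        for edges in powerset(all_pairs(n))
        if oracle_acceptable(n, edges, strategies, game, isolated_rule)
    )


@pytest.fixture
def six_player_profile():
    from nashnets import StrategyProfile

    return StrategyProfile((1, 0, 1, 1, 0, 0))
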