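"""Named built-in scenarios, so every command is drivable without data files.

``six-*`` scenarios use the canonical six-player profile in which
players {1, 3, 4} contribute (strategy 1) and {2, 5, 6} do not.
``five-<game>-<n1>`` scenarios use five players with the stated number
of strategy-1 players (taken to be the lowest-numbered ones).
``random-<n>-<n1>-<seed>`` draws a uniformly random labeled profile
with the given composition, deterministically from the seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .core import DEFAULT_POLICY, EquilibriumPolicy, Game, StrategyProfile
from .errors import InputError

__all__ = ["Scenario", "FIXTURE_NAMES", "make_fixture"]

_SIX_PLAYER = (1, 0, 1, 1, 0, 0)


@dataclass(frozen=True)
class Scenario:
    name: str
    profile: StrategyProfile
    game: Game
    policy: EquilibriumPolicy = DEFAULT_POLICY
    notes: str = ""


def _five(n1: int) -> StrategyProfile:
    return StrategyProfile((1,) * n1 + (0,) * (5 - n1))


_FIXED: dict[str, Scenario] = {
    s.name: s
    for s in [
        Scenario(
            "six-majority",
            StrategyProfile(_SIX_PLAYER),
            Game.MAJORITY,
            notes="six players, V1={1,3,4}",
        ),
        Scenario(
            "six-minority",
            StrategyProfile(_SIX_PLAYER),
            Game.MINORITY,
            notes="six players, V1={1,3,4}",
        ),
        Scenario(
            "six-bestshot",
            StrategyProfile(_SIX_PLAYER),
            Game.BEST_SHOT,
            notes="six players, V1={1,3,4}",
        ),
        Scenario("five-majority-0", _five(0), Game.MAJORITY),
        Scenario("five-majority-5", _five(5), Game.MAJORITY),
        Scenario("five-bestshot-1", _five(1), Game.BEST_SHOT),
        Scenario("five-minority-2", _five(2), Game.MINORITY),
        Scenario("five-minority-3", _five(3), Game.MINORITY),
    ]
}

FIXTURE_NAMES = tuple(_FIXED) + ("random-<n>-<n1>-<seed>",)

_RANDOM_RE = re.compile(r"^random-(\d+)-(\d+)-(\d+)$")


def make_fixture(name: str) -> Scenario:
    """Return the named scenario; raise listing valid names otherwise.

    Random scenarios carry no game; they default to the majority game.
    """
    if name in _FIXED:
        return _FIXED[name]
    match = _RANDOM_RE.match(name)
    if match:
        n, n1, seed = (int(g) for g in match.groups())
        if n < 1 or not 0 <= n1 <= n:
            raise InputError(f"bad composition in fixture {name!r}")
        rng = np.random.default_rng(seed)
        ones = rng.choice(n, size=n1, replace=False)
        strategies = tuple(1 if i in set(ones.tolist()) else 0 for i in range(n))
        return Scenario(
            name,
            StrategyProfile(strategies),
            Game.MAJORITY,
            notes=f"random profile, n={n}, n1={n1}, seed={seed}",
        )
    raise InputError(
        f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
    )
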