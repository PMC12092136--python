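"""Exception hierarchy for nashnets."""


class NashNetsError(Exception):
    """Base class for all package errors."""


class InputError(NashNetsError, ValueError):
    """Malformed or inconsistent user input (sizes, values, files)."""


class DomainError(NashNetsError, ValueError):
    """Argument outside the mathematical domain of an operation."""


class UnsupportedGameError(NashNetsError):
    """Operation not defined for the requested game."""


class NoClosedFormError(NashNetsError):
    """No closed-form count exists; caller must enumerate."""

    def __init__(self, game: str, n0: int, n1: int) -> None:
        super().__init__(
            f"no closed-form count for game={game} at (n0={n0}, n1={n1}); "
            "use enumeration mode"
        )
        self.game = game
        self.n0 = n0
        self.n1 = n1


class ResourceLimitError(NashNetsError):
    """A configured ceiling (graph-space size, output size) would be exceeded."""


class NonConvergenceError(NashNetsError):
    """A random walk hit its step guard before absorption."""

    def __init__(self, steps: int, start_mask: int | None = None) -> None:
        super().__init__(f"walk not absorbed after {steps} steps")
        self.steps = steps
        self.start_mask = start_mask
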