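"""Exception types shared across the package."""


class RDistanceError(Exception):
    """Base class for errors raised by this package."""


class GraphFormatError(RDistanceError):
    """A graph file is malformed or inconsistent."""


class BeyondCriticalGainError(RDistanceError):
    """The requested gain is at or beyond the convergence radius of the
    resolvent series (rho(X(gamma)) >= 1); the linear system does not
    represent walk counts there."""


class InfeasibleGammaError(RDistanceError):
    """No gain value satisfies all requested bounds simultaneously."""


class NavigationError(RDistanceError):
    """Greedy descent cannot take a step (no successors, or the goal is
    unreachable from every successor)."""


class DivergenceError(RDistanceError):
    """The recurrent circuit iteration diverges (rho(gamma * A) >= 1)."""
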