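"""Typed exceptions raised by the library.

Structural violations (a reaction network outside the unit-transfer class,
a degenerate projected state space, a level function that is not actually a
coclique function for the given space) are distinguished from numerical
failures (an unreachable first-passage target) so callers can react per case.
"""


class ScrnLevelsError(Exception):
    """Base class for all library errors."""


class InvalidNetworkError(ScrnLevelsError):
    """The reaction network violates a basic structural invariant."""


class UnitTransferError(ScrnLevelsError):
    """A reaction vector is not of unit-transfer form (one +1, one -1, rest 0)."""

    def __init__(self, violators):
        self.violators = list(violators)
        super().__init__(
            f"network is not unit-transfer; offending reaction vectors: "
            f"{[tuple(int(e) for e in v) for v in self.violators]}"
        )


class NonBipartiteError(ScrnLevelsError):
    """A bipartite structure was requested for a non-bipartite component."""


class NoSolutionError(ScrnLevelsError):
    """The sign-pattern linear system admits no solution."""


class InternalConsistencyError(ScrnLevelsError):
    """An exact-arithmetic invariant failed (should never happen)."""


class DegenerateSpaceError(ScrnLevelsError):
    """The projected state space has at most one state."""


class LiftError(ScrnLevelsError):
    """A projected state cannot be lifted to non-negative species counts."""


class NotCocliqueError(ScrnLevelsError):
    """A candidate level function admits a transition within a level set."""


class EmptyLevelError(ScrnLevelsError):
    """An intermediate level set is empty; the bound construction is undefined."""


class FeasibilityError(ScrnLevelsError):
    """The bounding-chain feasibility assumption fails: some non-extreme state
    has no in-space move in the required direction."""


class UndefinedBoundError(ScrnLevelsError):
    """A birth-death bound is undefined because a required rate is zero."""


class UnreachableTargetError(ScrnLevelsError):
    """The first-passage target is unreachable from part of the state space."""


class ConfigurationError(ScrnLevelsError):
    """Fixture or CLI parameters violate their defining identities."""
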