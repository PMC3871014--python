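"""Exception hierarchy for spinestats."""


class SpineStatsError(Exception):
    """Base class for all spinestats errors."""


class StructuralError(SpineStatsError):
    """The input graph is not a single rooted tree (cycle, extra root, disconnect)."""


class ValidationError(SpineStatsError):
    """An argument violates a documented precondition."""


class UndefinedStatisticError(SpineStatsError):
    """A statistic is requested for a pattern too small to define it (e.g. K with N < 2)."""


class ConvergenceError(SpineStatsError):
    """An iterative fit failed to converge within its iteration budget."""


class SampleShortageError(SpineStatsError):
    """A balanced sample was requested but a type has too few eligible spines."""

    def __init__(self, spine_type: str, available: int, requested: int):
        self.spine_type = spine_type
        self.available = available
        self.requested = requested
        super().__init__(
            f"type {spine_type!r} has only {available} eligible spines, "
            f"{requested} requested"
        )


class InsufficientNeighborsError(SpineStatsError):
    """A spine does not have enough same-tree neighbors for the requested k."""
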