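"""Exception hierarchy for cgbeads."""


class CGBeadsError(Exception):
    """Base class for all cgbeads errors."""


class EmptyInputError(CGBeadsError, ValueError):
    """No usable points remain after filtering (e.g. zero heavy atoms)."""


class SingularityError(CGBeadsError, ValueError):
    """Two interaction sites coincide; the repulsive term diverges."""


class ConditioningError(CGBeadsError, ValueError):
    """A linear system is singular or too ill-conditioned to solve reliably."""


class ConnectivityError(CGBeadsError, ValueError):
    """The elastic network is disconnected at the chosen cutoff."""


class InfeasibleConfigError(CGBeadsError, ValueError):
    """The run configuration cannot be satisfied (e.g. more beads than points)."""


class UndefinedCorrelationError(CGBeadsError, ValueError):
    """Cross-correlation undefined because one of the maps has zero variance."""
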