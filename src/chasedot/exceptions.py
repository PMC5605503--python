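"""Exception types raised across the package."""


class ChasedotError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ChasedotError, ValueError):
    """A configuration value or argument is out of its valid range."""


class DegenerateGeometryError(ChasedotError, ValueError):
    """A geometric operation received coincident or otherwise degenerate input."""


class InitializationError(ChasedotError, RuntimeError):
    """Rejection sampling of a valid initial state exhausted its retries."""


class ConditionMismatchError(ChasedotError, ValueError):
    """A cue generator was applied to a trial of the wrong condition."""


class InvalidPairError(ChasedotError, ValueError):
    """A pair statistic was requested for a dot that is not visible."""


class ConsistencyError(ChasedotError, ValueError):
    """Design table and cohort do not describe the same participants."""


class SeparationError(ChasedotError, RuntimeError):
    """Complete separation: the logistic likelihood has no finite maximum."""


class NotConvergedError(ChasedotError, RuntimeError):
    """An operation required a converged model fit but got an unconverged one."""


class UndefinedFAError(ChasedotError, ValueError):
    """A false-alarm rate was requested for a cell with no chase-absent trials."""
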