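"""Exception hierarchy shared across the package."""


class MirswitchError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MirswitchError, ValueError):
    """Input values violate a documented precondition."""


class InsufficientDataError(MirswitchError, ValueError):
    """Too few observations to attempt the requested fit."""


class FitFailureError(MirswitchError, RuntimeError):
    """A fit could not converge or the data are degenerate/non-identifiable."""


class OutOfDomainError(MirswitchError, ValueError):
    """Argument outside the mathematical domain of the operation."""


class DegenerateInputError(MirswitchError, ValueError):
    """Input with zero variance or otherwise degenerate structure."""


class ModelInapplicableError(MirswitchError, RuntimeError):
    """The requested model regime does not hold for the given parameters."""
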