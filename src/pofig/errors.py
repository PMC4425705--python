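"""Exception types shared across the package."""


class PofigError(Exception):
    """Base class for package errors."""


class DomainError(PofigError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class ConfigurationError(PofigError, ValueError):
    """A prior, effect model, or analysis configuration is inconsistent."""


class NumericalError(PofigError, RuntimeError):
    """A quadrature or other numerical routine failed to converge."""


class SumstatsError(PofigError, ValueError):
    """A summary-statistics table failed validation.

    Carries the offending line numbers (1-based, counting the header) so a
    user can locate the bad rows in the original file.
    """

    def __init__(self, message, lines=None):
        super().__init__(message)
        self.lines = tuple(lines) if lines else ()
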