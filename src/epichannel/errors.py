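"""Exception hierarchy shared across the pipeline."""


class EpichannelError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(EpichannelError):
    """A city/epidemic/simulation specification violates its invariants."""


class InvalidWindowError(EpichannelError):
    """Aggregation window is smaller than 1 or longer than the series."""


class InvalidCountError(EpichannelError):
    """Negative birth or death counts."""


class DataIntegrityError(EpichannelError):
    """Duplicate keys with conflicting values, or group-bound violations."""


class InsufficientHistoryError(EpichannelError):
    """No usable baseline history for the requested study year."""


class ValidationError(EpichannelError):
    """Input file fails schema validation.

    Carries a short machine-readable ``code`` and, when known, the 1-based
    data row number the problem was found in.
    """

    def __init__(self, message: str, code: str = "invalid", row: int | None = None):
        super().__init__(message)
        self.code = code
        self.row = row


class ConfigError(EpichannelError):
    """Run configuration file is malformed or out of range."""
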