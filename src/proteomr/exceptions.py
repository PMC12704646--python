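"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigurationError -> 2, everything
else raised by validation -> 1.
"""


class ProteomrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ProteomrError):
    """A missing/invalid configuration key, column mapping, or input path."""


class ValidationError(ProteomrError):
    """Input data violating a schema or invariant (carries row context when known)."""

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class UndefinedRatioError(ProteomrError):
    """Wald ratio requested with a zero exposure effect."""


class InsufficientInstrumentsError(ProteomrError):
    """An estimator was called with fewer instruments than it requires."""


class OrientationError(ProteomrError):
    """Trial log2-fold change of exactly zero has no direction to orient to."""
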