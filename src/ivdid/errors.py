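"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input series, table, or parameter set violates a contract."""


class CoverageError(ValidationError):
    """A series does not cover the requested study window.

    Carries the missing dates so callers can report exactly what is absent.
    """

    def __init__(self, message: str, missing=None):
        super().__init__(message)
        self.missing = list(missing) if missing is not None else []


class SingularDesignError(ValueError):
    """A regression design matrix is rank deficient."""

    def __init__(self, message: str, collinear=None):
        super().__init__(message)
        self.collinear = list(collinear) if collinear is not None else []


class WeakInstrumentError(RuntimeError):
    """The instrument has (almost) no partial association with the exposure."""
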