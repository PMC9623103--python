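"""Exception hierarchy shared across the package."""


class TsmrError(Exception):
    """Base class for all package errors."""


class FormatError(TsmrError):
    """A file could not be parsed into the canonical schema."""


class ValidationError(TsmrError):
    """A record or table violates a schema invariant."""


class InsufficientInstrumentsError(TsmrError):
    """Too few instruments survive for the requested operation.

    Carries ``stage`` so pipeline failures can name the filter responsible.
    """

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message)
        self.stage = stage
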