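"""Exception hierarchy shared across the pipeline."""


class FastrataError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FastrataError, ValueError):
    """A file or table does not conform to the expected layout."""


class FitError(FastrataError, RuntimeError):
    """A model fit failed to converge; carries diagnostics in ``details``."""

    def __init__(self, message: str, details: dict | None = None):
        super().__init__(message)
        self.details = details or {}


class GeometryError(FastrataError, ValueError):
    """A geometric configuration is impossible (e.g. |dz| > molecule length)."""
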