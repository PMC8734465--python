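"""Exception hierarchy shared across the package."""


class StandppError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(StandppError):
    """A required column or field is missing from an input table."""


class RowParseError(StandppError):
    """A table row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class RasterFormatError(StandppError):
    """An ASCII raster header or body is malformed."""


class DomainError(StandppError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class EstimationError(StandppError):
    """A spatial statistic cannot be estimated from the given pattern."""


class AllometryLookupError(StandppError, KeyError):
    """No allometry entry (and no fallback) exists for a species."""


class ConfigurationError(StandppError):
    """Inconsistent or invalid analysis configuration."""
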