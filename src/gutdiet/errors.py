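"""Exception hierarchy for the gut-content analysis pipeline."""


class GutDietError(Exception):
    """Base class for all package errors."""


class SchemaError(GutDietError):
    """An input file is missing required columns or has an unusable layout."""


class ValidationError(GutDietError):
    """Rows in an input file violate the record invariants.

    Carries the offending 1-based file row numbers in :attr:`rows`.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        self.rows = rows or []
        if self.rows:
            message = f"{message} (rows: {', '.join(map(str, self.rows))})"
        super().__init__(message)


class ConfigurationError(GutDietError):
    """A policy, threshold, or config value is missing or out of range."""


class EmptyGroupError(GutDietError):
    """A group has no fish with gut contents; indices are undefined."""
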