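"""Exception hierarchy for the lepmem pipeline.

All pipeline errors derive from :class:`LepmemError` so the CLI can map any
data/analysis failure to a single exit code.
"""


class LepmemError(Exception):
    """Base class for all lepmem errors."""


class ConfigError(LepmemError):
    """A configuration field is missing, out of range, or inconsistent."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class SchemaError(LepmemError):
    """An input table violates the documented CSV schema.

    Carries the offending row index (0-based, data rows) and column when known.
    """

    def __init__(self, message: str, row=None, column=None):
        self.row = row
        self.column = column
        loc = ""
        if row is not None or column is not None:
            loc = f" (row={row}, column={column})"
        super().__init__(message + loc)


class StructuralError(LepmemError):
    """Tables are individually valid but mutually inconsistent (e.g. mismatched
    rosters, duplicated participant×image cells)."""


class SeparationError(LepmemError):
    """Complete separation detected while fitting a logistic mixed model."""


class NotConvergedError(LepmemError):
    """An operation requiring a converged model fit received one that is not."""


class DegenerateDataError(LepmemError):
    """Input is degenerate for the requested statistic (e.g. constant vector
    for a correlation, too few images for a quadrant analysis)."""
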