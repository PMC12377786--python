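"""Exception hierarchy shared across the package.

Statistics with an empty denominator are never silently NaN: operations
either raise one of these errors or return ``None`` for an individual
undefined quantity (the "undefined marker" convention used throughout).
"""


class GdmSimError(Exception):
    """Base class for all package errors."""


class ValidationError(GdmSimError, ValueError):
    """An input value violates a documented precondition.

    The message names the offending field or argument.
    """


class SchemaError(ValidationError):
    """A tabular input is missing required columns."""

    def __init__(self, missing, source=""):
        self.missing = sorted(missing)
        where = f" in {source}" if source else ""
        super().__init__(f"missing required columns{where}: {', '.join(self.missing)}")


class AlignmentError(ValidationError):
    """Parallel vectors have mismatched lengths."""


class ConvergenceError(GdmSimError):
    """An iterative numerical routine failed to converge."""
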