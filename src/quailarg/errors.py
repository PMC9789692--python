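"""Exception hierarchy shared across the package."""


class QuailArgError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(QuailArgError):
    """A required column is missing from an input table."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"required column missing from input table: {column!r}")


class ParseError(QuailArgError):
    """A cell could not be parsed as a number."""

    def __init__(self, row: int, column: str, value):
        self.row = row
        self.column = column
        self.value = value
        super().__init__(
            f"non-numeric value {value!r} in column {column!r} at row {row}"
        )


class DomainError(QuailArgError):
    """An input violates a physical/biological constraint (e.g. negative intake)."""


class DesignError(QuailArgError):
    """The experimental design cannot support the requested analysis."""


class FitError(QuailArgError):
    """Nonlinear fit failed to converge; carries the best candidate found."""

    def __init__(self, message: str, best=None, diagnostics=None):
        self.best = best
        self.diagnostics = diagnostics or {}
        super().__init__(message)
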