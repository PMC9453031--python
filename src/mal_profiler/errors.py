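"""Exception hierarchy.

Validation failures (bad input data, inconsistent configuration) are kept
distinct from runtime failures (a model that cannot be fitted) so the CLI
can map them onto different exit codes.
"""


class MalProfilerError(Exception):
    """Base class for all package errors."""


class ValidationError(MalProfilerError):
    """Input data or configuration violates a stated contract."""


class EmptyInputError(ValidationError):
    """An operation that requires a non-empty cohort received none."""


class SchemaError(ValidationError):
    """A cohort file violates the column schema; carries row/column info."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        super().__init__(f"{message}" + (f" ({', '.join(loc)})" if loc else ""))


class ConfigurationError(ValidationError):
    """A battery or pipeline configuration references unknown variables."""


class InfeasibleFixtureError(ValidationError):
    """A fixture specification cannot be realized; names the constraint."""


class InsufficientDataError(MalProfilerError):
    """Too few observations to run a test or fit a model."""


class SeparationError(MalProfilerError):
    """A logistic-model group contains a single outcome class."""


class NonIdentifiableError(MalProfilerError):
    """A regression predictor is constant within a group."""
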