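"""Exception hierarchy.

Input problems (bad tables, bad pathway files, bad configuration) raise
subclasses of :class:`InputError`; internal contract violations raise
:class:`MagdietError` directly. The CLI maps InputError to exit status 1
and anything else to 2.
"""


class MagdietError(Exception):
    """Base class for all package errors."""


class InputError(MagdietError):
    """A problem with user-supplied input (file, table, configuration)."""


class SchemaError(InputError):
    """A table is missing a required column or carries an unknown token."""


class TableParseError(InputError):
    """A cell failed to parse; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        super().__init__(message if row is None else f"row {row}: {message}")


class UniquenessError(InputError):
    """Duplicate identifier where uniqueness is required."""


class ValidationError(InputError):
    """A value violates a documented domain invariant."""


class PathwayDefinitionError(InputError):
    """A pathway definition is structurally invalid (bad category/steps)."""


class ReferenceResolutionError(PathwayDefinitionError):
    """A composite pathway references an unknown member pathway."""


class CycleError(PathwayDefinitionError):
    """Composite pathway membership contains a cycle."""


class JoinError(InputError):
    """Identifiers in one table do not match the companion table."""


class DesignError(InputError):
    """A statistical design is unusable (unlabeled rows, tiny groups)."""


class DegenerateDataError(InputError):
    """Data admit no answer (zero total coverage, constant matrix, ...)."""


class ConfigurationError(InputError):
    """A rule configuration is incomplete or out of range."""
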