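"""Exception hierarchy.

Contract violations (caller errors) and data/format problems are kept
distinct so that the CLI can map them to stage-labelled exit messages.
"""


class VirtualControlsError(Exception):
    """Base class for all package errors."""


class SchemaError(VirtualControlsError):
    """A file or table does not have the columns the schema requires."""


class CohortValidationError(VirtualControlsError):
    """Rows violate type or value constraints; carries row diagnostics."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class FormatError(VirtualControlsError):
    """A coefficient-set or config file is unreadable or malformed."""


class ContractError(VirtualControlsError):
    """A precondition of an operation was violated by the caller."""


class SingularityError(VirtualControlsError):
    """Rank-deficient design matrix; names the collinear columns."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class ConvergenceError(VirtualControlsError):
    """Iterative fit failed to converge (reports iteration count)."""

    def __init__(self, message, iterations=None):
        super().__init__(message)
        self.iterations = iterations


class InsufficientDataError(VirtualControlsError):
    """Too few subjects for the requested estimate."""


class AccrualError(VirtualControlsError):
    """Selection so extreme that the single-arm cohort cannot accrue."""


class ConfigurationError(VirtualControlsError):
    """A scenario or run configuration is internally inconsistent."""


class AlignmentError(VirtualControlsError):
    """Subject ids of two inputs do not align."""
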