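"""Exception hierarchy shared across the package."""

from __future__ import annotations


class HXMSError(Exception):
    """Base class for all hxmsio errors."""


class FormatError(HXMSError):
    """A line or token of an HXMS file (or M/Z field) matches no known shape.

    Parameters
    ----------
    message:
        Human-readable description.
    line:
        1-based line number within the source, when known.
    token:
        The offending token, when the error is token-scoped.
    """

    code = "FORMAT_ERROR"

    def __init__(self, message: str, *, line: int | None = None, token: str | None = None):
        self.line = line
        self.token = token
        if line is not None:
            message = f"line {line}: {message}"
        if token is not None:
            message = f"{message} (token: {token!r})"
        super().__init__(message)


class SchemaError(HXMSError):
    """A vendor-export table is missing required columns or is malformed."""

    code = "SCHEMA_ERROR"

    def __init__(self, message: str, *, column: str | None = None, row: int | None = None):
        self.column = column
        self.row = row
        if column is not None:
            message = f"{message} (column: {column!r})"
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class MissingZeroError(HXMSError):
    """No 0 s timepoint exists in any replicate of a peptide, so deuterium
    uptake cannot be referenced."""

    code = "MISSING_ZERO"

    def __init__(self, message: str = "no 0 s timepoint in any replicate", *, peptide=None):
        self.peptide = peptide
        if peptide is not None:
            message = f"{message} (peptide: {peptide})"
        super().__init__(message)


class DatasetValidationError(HXMSError):
    """Raised by the writer when asked to serialize a dataset that carries
    error-severity validation violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        codes = ", ".join(sorted({v.code for v in self.violations}))
        super().__init__(
            f"dataset has {len(self.violations)} error-severity violation(s): {codes}; "
            "run validate_dataset and repair before writing"
        )
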