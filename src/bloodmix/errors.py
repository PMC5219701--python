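"""Exception hierarchy.

Validation failures (bad files, broken invariants, misaligned identifiers)
raise :class:`ValidationError` subclasses so callers can distinguish user
input problems (CLI exit code 1) from runtime faults (exit code 2).
"""


class BloodmixError(Exception):
    """Base class for all package errors."""


class ValidationError(BloodmixError):
    """An object or file violates a documented invariant."""


class FormatError(ValidationError):
    """A file is structurally malformed (duplicate ids, bad header...)."""


class ParseError(FormatError):
    """A cell could not be parsed; carries row/column coordinates."""

    def __init__(self, message: str, row=None, column=None):
        super().__init__(message)
        self.row = row
        self.column = column


class AlignmentError(ValidationError):
    """Two objects that must share identifiers do not."""


class EmptyFeatureSetError(ValidationError):
    """A filter or intersection removed every feature."""


class InsufficientSignatureError(ValidationError):
    """Feature intersection with a basis matrix is smaller than the
    number of cell types, so the mixture system is underdetermined."""


class MissingFeatureError(ValidationError):
    """A model feature is absent from the supplied expression matrix."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            f"{len(self.missing)} model feature(s) missing from expression "
            f"matrix: {', '.join(self.missing[:10])}"
            + ("..." if len(self.missing) > 10 else "")
        )


class EmptyMarkerError(ValidationError):
    """No feature passed the marker-selection rule."""


class DegenerateDataError(ValidationError):
    """Data admit no meaningful fit (e.g. constant responses)."""


class UndefinedCorrelationError(BloodmixError):
    """Correlation requested on a constant (zero-variance) vector."""


class ConfigError(ValidationError):
    """A configuration object is internally inconsistent."""
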