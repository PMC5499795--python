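"""Exception hierarchy for rbdkit.

All rbdkit errors derive from :class:`RbdkitError` so callers can catch the
whole family with one clause while keeping fine-grained types for tests and
pipeline stage reporting.
"""


class RbdkitError(Exception):
    """Base class for all rbdkit errors."""


class InputError(RbdkitError):
    """A required input file is missing or unreadable."""


class MalformedRecordError(RbdkitError):
    """A data row violates the expected table layout.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PatternError(RbdkitError):
    """A keyword regular-expression pattern failed to compile."""


class AlphabetError(RbdkitError):
    """A sequence contains characters outside the amino-acid alphabet."""


class UndefinedInputError(RbdkitError):
    """An operation received degenerate input for which it is undefined."""


class ShortSequenceError(RbdkitError):
    """A sequence is shorter than the k-mer size requested."""


class DimensionError(RbdkitError):
    """Vector operands have mismatched lengths."""


class CoordinateError(RbdkitError):
    """Hit coordinates are inconsistent with the reference domain."""


class ScoringUnavailableError(RbdkitError):
    """Feature scoring is impossible (e.g. reference lacks a consensus)."""


class DegenerateLabelsError(RbdkitError):
    """Classifier evaluation needs both classes present."""


class ShapeError(RbdkitError):
    """An alignment passed to profile building has ragged rows."""


class ConfigError(RbdkitError):
    """A configuration value is inconsistent or impossible to satisfy."""
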