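"""Exception hierarchy for the tfinteract package.

All package-specific failures derive from :class:`TFInteractError` so callers
(and the CLI) can distinguish user-facing input problems from internal bugs.
"""


class TFInteractError(Exception):
    """Base class for all errors raised by tfinteract."""


class AAIndexParseError(TFInteractError):
    """Malformed AAIndex1 record (names the accession and line number)."""

    def __init__(self, message: str, accession: str | None = None,
                 line: int | None = None):
        loc = []
        if accession:
            loc.append(f"accession {accession!r}")
        if line is not None:
            loc.append(f"line {line}")
        suffix = f" ({', '.join(loc)})" if loc else ""
        super().__init__(message + suffix)
        self.accession = accession
        self.line = line


class InvalidSequenceError(TFInteractError):
    """Sequence contains characters outside the accepted amino-acid alphabet."""


class DegenerateSequenceError(TFInteractError):
    """Sequence too short to be split into non-empty terminal segments."""


class UndefinedMeanError(TFInteractError):
    """A segment contains no countable residues (all X/U)."""


class MissingSequenceError(TFInteractError):
    """A protein identifier referenced by a pair table has no sequence."""


class CapacityError(TFInteractError):
    """Fewer eligible pairs exist than were requested."""

    def __init__(self, message: str, capacity: int):
        super().__init__(message)
        self.capacity = capacity


class SingularCovarianceError(TFInteractError):
    """A class covariance matrix is singular after regularization."""

    def __init__(self, message: str, class_label=None):
        super().__init__(message)
        self.class_label = class_label


class StratificationError(TFInteractError):
    """Fold construction impossible (k < 2 or a class smaller than k)."""


class FeasibilityError(TFInteractError):
    """Requested synthetic effect size unreachable with valid compositions."""


class AnnotationMismatchError(TFInteractError):
    """Model feature annotation does not match the supplied property table."""
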