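"""Exception hierarchy shared across the package."""


class PlastarchError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PlastarchError):
    """A file could not be parsed as the expected format."""


class IntegrityError(PlastarchError):
    """Parsed data violates an internal consistency requirement."""


class UnsupportedInputError(PlastarchError):
    """The operation is undefined for this kind of input."""


class FrameError(PlastarchError):
    """A coding sequence is not a whole number of codons."""


class UndefinedValueError(PlastarchError):
    """A statistic is undefined for the given data (e.g. no codons)."""


class CapacityError(PlastarchError):
    """A generator could not satisfy its placement constraints."""


class DisambiguationError(PlastarchError):
    """Duplicate gene symbols prevent building a signed gene order."""


class ReconciliationError(PlastarchError):
    """Taxon labels in a matrix could not be matched to tree leaves."""


class UndefinedDistanceError(PlastarchError):
    """A gene-order distance is undefined (fewer than two shared genes)."""
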