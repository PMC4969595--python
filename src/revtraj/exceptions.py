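"""Exception hierarchy.

Every distinct failure mode named by the I/O and classification contracts
gets its own class so callers can catch them individually; all inherit
from :class:`RevtrajError`.
"""


class RevtrajError(Exception):
    """Base class for all revtraj errors."""


class MatrixFormatError(RevtrajError):
    """A matrix file contains a non-numeric body cell or is structurally broken."""


class DuplicateIdentifierError(RevtrajError):
    """Duplicate gene or condition identifiers in a matrix."""


class EmptyMatrixError(RevtrajError):
    """A matrix with zero genes or zero conditions."""


class InvalidValueError(RevtrajError):
    """Negative, non-finite, or otherwise inadmissible numeric values."""


class UnknownConditionError(RevtrajError, KeyError):
    """A condition identifier not present in the matrix."""


class GeneSetFormatError(RevtrajError):
    """A malformed GMT line (fewer than 3 tab-separated fields) or empty file."""


class GeneMismatchError(RevtrajError):
    """Two per-gene tables that must cover the same genes in the same order do not."""


class ConfigError(RevtrajError, ValueError):
    """A configuration field violates its declared invariant."""
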