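"""Exception hierarchy for cgenet.

Every error raised by the package derives from :class:`CgenetError` so callers
can catch the package's failures with one clause. Validation errors carry the
offending rows/regions in their message.
"""


class CgenetError(Exception):
    """Base class for all cgenet errors."""


class MissingColumn(CgenetError):
    """An expression file lacks one of the required header columns."""


class UnknownRegion(CgenetError):
    """A region id does not resolve against the region registry."""


class DuplicateMeasurement(CgenetError):
    """More than one value for the same (subject, gene, region)."""


class NonNumericValue(CgenetError):
    """An expression value could not be parsed as a finite number."""


class IoFailure(CgenetError):
    """A file could not be written."""


class InfeasibleSpec(CgenetError):
    """A covariance specification cannot be realized as a PSD correlation
    matrix within the repair tolerance."""


class InsufficientSubjects(CgenetError):
    """Fewer than 4 complete subjects in a group (Fisher SE needs n > 3)."""


class ZeroVariance(CgenetError):
    """A region has zero variance across subjects (reported, not raised)."""


class DomainError(CgenetError):
    """An argument outside the mathematical domain of an operation."""


class EmptyNetwork(CgenetError):
    """A network with no non-zero edges where edges are required."""


class EmptyInput(CgenetError):
    """An empty collection where at least one element is required."""


class TooLarge(CgenetError):
    """Brute-force partition search requested on more than 10 nodes."""


class RegionMismatch(CgenetError):
    """Two networks being compared do not share the same region set."""


class MissingLayout(CgenetError):
    """A region lacks layout coordinates required for rendering."""


class UnsupportedFormat(CgenetError):
    """An export format outside {graphml, edgelist, csv}."""
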