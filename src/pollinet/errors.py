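"""Exception hierarchy for pollinet.

Every error raised by the package derives from :class:`PollinetError` so
callers can catch pipeline failures with a single except clause while tests
can still discriminate the failure mode.
"""


class PollinetError(Exception):
    """Base class for all pollinet errors."""


class FormatError(PollinetError):
    """A file could not be parsed (missing columns, malformed matrix layout)."""


class ValidationError(PollinetError):
    """A parsed value violates a domain invariant (e.g. negative visit count)."""


class EmptySelectionError(PollinetError):
    """A record selector matched nothing; distinct from a valid all-zero web."""


class UndefinedMetricError(PollinetError):
    """A metric is mathematically undefined for this input (e.g. evenness of a
    single-link web, generalism of an unobserved morphotype)."""


class DegenerateTableError(PollinetError):
    """A contingency table has a zero row or column marginal."""


class AlignmentError(PollinetError):
    """Two labelled structures could not be aligned (label mismatch)."""


class InsufficientReplicationError(PollinetError):
    """A group comparison was requested with fewer than two replicates."""


class ConfigurationError(PollinetError):
    """A configuration object is inconsistent (e.g. unmapped plant species)."""
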