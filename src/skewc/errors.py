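"""Exception hierarchy for skewc.

Every user-facing failure derives from :class:`SkewCError` so the CLI can
catch one type and exit non-zero with a clean message.
"""


class SkewCError(Exception):
    """Base class for all skewc errors."""


class InputError(SkewCError):
    """Missing/unreadable input file or directory."""


class FormatError(SkewCError):
    """Malformed content in an otherwise readable input."""


class ParameterError(SkewCError):
    """Inadmissible parameter value (e.g. alpha out of range)."""


class DegenerateDataError(SkewCError):
    """Data carry no usable signal (all points identical, all cells empty)."""


class StaleIndexError(SkewCError):
    """A persisted bin index does not match the gene model it is loaded for."""
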