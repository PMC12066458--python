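"""Exception hierarchy for agrocf.

All validation problems raise :class:`ValidationError` (a ``ValueError``),
file-structure problems raise :class:`FormatError`, and statistics that need
a minimum number of observations raise :class:`InsufficientDataError`.
"""


class AgroCFError(Exception):
    """Base class for all agrocf errors."""


class ValidationError(AgroCFError, ValueError):
    """A domain invariant was violated (negative quantity, fraction > 1, ...)."""


class FormatError(AgroCFError, ValueError):
    """An input file does not have the expected structure."""


class InsufficientDataError(AgroCFError, ValueError):
    """Too few observations for the requested statistic."""


class UndefinedRatioError(AgroCFError, ZeroDivisionError):
    """A ratio-type quantity was requested with a zero denominator."""
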