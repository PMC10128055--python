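"""Exception hierarchy for the pipeline.

Every error raised deliberately by this package derives from
:class:`SipTraitsError`, so callers can catch one type at the CLI boundary.
"""


class SipTraitsError(Exception):
    """Base class for all package errors."""


class FormatError(SipTraitsError):
    """A file is missing a required column or is otherwise malformed."""


class ParseError(SipTraitsError):
    """A cell could not be parsed; message cites the offending line."""


class IntegrityError(SipTraitsError):
    """Duplicate identifiers or other within-table inconsistencies."""


class ReferentialError(SipTraitsError):
    """A record references an identifier that does not exist."""


class ValidationError(SipTraitsError):
    """An argument violates a documented precondition."""


class UndefinedStatisticError(SipTraitsError):
    """A statistic is undefined for the given input (e.g. zero variance)."""
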