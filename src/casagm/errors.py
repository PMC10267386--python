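"""Exception hierarchy shared across the package."""


class CasagmError(Exception):
    """Base class for all package errors."""


class FormatError(CasagmError):
    """A file does not conform to its declared on-disk format."""


class ParseError(FormatError):
    """A cell or token could not be parsed as a number."""


class IntegrityError(CasagmError):
    """An encoded object violates its structural invariants."""


class DegenerateDataError(CasagmError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class SpecError(CasagmError):
    """A generator or benchmark specification is self-inconsistent."""
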