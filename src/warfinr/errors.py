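"""Exception hierarchy.

All domain failures derive from :class:`WarfinrError` so callers can catch
one base class; the CLI maps them onto non-zero exit codes.
"""


class WarfinrError(Exception):
    """Base class for all domain errors raised by this package."""


class DomainError(WarfinrError, ValueError):
    """An input lies outside the mathematical domain of an operation
    (non-positive INR or factor VII, dose <= 0, reversed interval ...)."""


class ValidityError(WarfinrError, ValueError):
    """An input violates a clinical-validity guard rail, e.g. a sample drawn
    before factor VII has equilibrated (first two days of therapy)."""


class InversionError(WarfinrError, RuntimeError):
    """The reference-dose inversion has no solution: the observed slope is
    non-positive (patient at or beyond steady state, or invalid data) or no
    sign change exists inside the search bracket."""


class FitError(WarfinrError, RuntimeError):
    """A calibration fit failed: degenerate data, under-determined problem,
    or non-convergence after the bounded multi-start schedule."""


class ParseError(WarfinrError, ValueError):
    """A data file could not be parsed; the message names the offending
    line or column."""
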