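"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`SpinemultError`, so callers (and the CLI) can distinguish
data/validation problems from programming errors.
"""


class SpinemultError(Exception):
    """Base class for all errors raised by spinemult."""


class DomainError(SpinemultError, ValueError):
    """An input value is outside the domain an operation accepts
    (negative length, months out of range, bad mode string, ...)."""


class UnderAgeError(DomainError):
    """Requested age lies below the first tabulated age for that sex."""


class OverAgeError(DomainError):
    """Requested age lies beyond skeletal maturity and clamping was not
    requested."""


class TableIntegrityError(SpinemultError):
    """A multiplier table violates a structural invariant (gaps in the
    monthly grid, non-monotone values, maturity multiplier != 1, ...)."""


class DerivationError(SpinemultError):
    """A growth database cannot yield multipliers (typically a missing
    maturity record for some sex/percentile curve)."""


class ParseError(SpinemultError):
    """A CSV input file is malformed; carries the offending line number
    when one is known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
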