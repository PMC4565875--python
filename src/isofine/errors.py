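"""Exception hierarchy."""


class IsofineError(Exception):
    """Base class for all package errors."""


class FormulaError(IsofineError):
    """Malformed chemical-formula string; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class UnsupportedElementError(IsofineError):
    """Element symbol not present in the active isotope table."""


class TableError(IsofineError):
    """Invalid isotope table (abundances, ordering, offsets)."""


class TruncationError(IsofineError):
    """Requested probability coverage not attainable within the j window."""


class DomainError(IsofineError):
    """Argument outside the mathematical domain of an operation."""


class UndefinedSpacingError(IsofineError):
    """Mean peak spacing undefined (fewer than two fine peaks)."""


class DegenerateRangeError(IsofineError):
    """Zero-width mass range cannot be binned."""


class BinningError(IsofineError):
    """Two binned distributions do not share bin edges."""
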