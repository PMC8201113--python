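"""Exception hierarchy shared across the package."""


class KanoqualError(Exception):
    """Base class for all package errors."""


class FormatError(KanoqualError, ValueError):
    """A file is structurally malformed (bad header, duplicate ids, ...)."""


class ValidationError(KanoqualError, ValueError):
    """Well-formed input with invalid content (code out of range, ...)."""


class UndefinedCoefficientError(KanoqualError, ArithmeticError):
    """CS/DS requested for an attribute whose A+O+M+I denominator is zero.

    Distinct from a coefficient that is numerically zero: with only
    questionable and reverse answers the Berger coefficients carry no
    information and must not be reported as 0.
    """


class ZeroVarianceItemError(KanoqualError, ValueError):
    """An item with no variance entered a correlation-based reliability
    computation."""

    def __init__(self, item: str):
        self.item = item
        super().__init__(f"item {item!r} has zero variance; "
                         "standardized alpha is undefined")
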