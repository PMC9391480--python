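"""Exception hierarchy shared across the package."""


class PrecsensError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(PrecsensError, ValueError):
    """A generator or model specification violates its invariants."""


class InsufficientDataError(PrecsensError, ValueError):
    """Too few valid months (or pixels) to carry out the operation."""


class AlignmentError(PrecsensError, ValueError):
    """Input series do not share a common length/index."""


class CollinearityError(PrecsensError, ValueError):
    """Regression design matrix is singular or near-singular."""


class NormalizationError(PrecsensError, ValueError):
    """A trend cannot be normalized because the reference mean is ~ 0."""


class ConditioningError(PrecsensError, ArithmeticError):
    """A numerical routine lost conditioning (singular update, underflow)."""
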