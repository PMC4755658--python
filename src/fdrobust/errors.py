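"""Exception types shared across the package."""


class FdrobustError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FdrobustError, ValueError):
    """Input data violates a structural invariant (duplicates, negatives, ...)."""


class ParseError(FdrobustError, ValueError):
    """A delimited-text cell could not be parsed; names the offending cell."""


class DegenerateInputError(FdrobustError, ValueError):
    """Input is structurally valid but the requested quantity is undefined
    (all-zero abundance vector, constant vector for skewness, ...)."""
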