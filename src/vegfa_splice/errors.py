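"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line/record."""


class NoProductError(ValueError):
    """In-silico PCR found no site for one of the primers."""


class NonUniquePrimingError(ValueError):
    """A primer matched the template at more than one site."""


class ZeroDenominatorError(ValueError):
    """A ratio or normalization was requested with a zero denominator."""
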