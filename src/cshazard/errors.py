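"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input fails a domain invariant (negative pressure, bad weight, ...)."""


class DialectError(ValidationError):
    """Input violates the rules of the active cohort dialect."""


class MissingDataError(ValidationError):
    """A required value is entirely missing."""


class DegenerateDataError(ValueError):
    """A fit was requested on data that cannot identify the model
    (e.g. a cohort with no cases, or no controls)."""


class NoMedianError(ValueError):
    """The (population) survival curve never reaches 0.5, so the median
    event age is undefined — e.g. a cure fraction above one half."""
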