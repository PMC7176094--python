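"""Exception types raised across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates an operation's precondition."""


class SchemaError(ValueError):
    """A tabular input is missing a required column or has the wrong shape."""


class EmptyDomainError(ValueError):
    """A domain restriction left no rows to aggregate over."""


class DegenerateSampleError(ValueError):
    """The combined sample contains only one membership class."""


class DegenerateWeightsError(ValueError):
    """Weights sum to zero, so no weighted mean exists."""


class UnclippedPropensityError(ValueError):
    """A propensity of exactly 0 or 1 reached an inverse-odds computation."""
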