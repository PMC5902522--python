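"""Exception types shared across the package."""


class DomainError(ValueError):
    """An input lies outside the mathematical domain of an operation."""


class DegeneratePriorError(DomainError):
    """Prior plausibility of 0 or 1: testing the assumption is redundant.

    A rational agent who is already certain that the assumption holds (or
    fails) gains nothing from running a check, and the Bayesian update is
    undefined at the boundary.
    """


class DegenerateDataError(ValueError):
    """Data carry no information for the requested statistic (e.g. zero spread)."""


class UndefinedRateError(ValueError):
    """A conditional rate has an empty conditioning event (e.g. no nonrejections)."""
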