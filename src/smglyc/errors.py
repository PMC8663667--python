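"""Exception hierarchy for smglyc.

All errors raised by the package derive from :class:`SmglycError` so callers
can catch package failures with a single except clause.
"""


class SmglycError(Exception):
    """Base class for all smglyc errors."""


class ValidationError(SmglycError, ValueError):
    """An input value violates a documented precondition.

    The message always names the offending field.
    """


class EmptySeriesError(SmglycError):
    """An HbA1c series has no measurement inside the requested year."""


class GenerationError(SmglycError):
    """The synthetic-data generator could not satisfy its tolerance."""


class SingularDesignError(SmglycError):
    """A regression design matrix is rank deficient.

    ``columns`` names the columns implicated in the collinearity.
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "singular design matrix; collinear columns: " + ", ".join(self.columns)
        )


class InsufficientDataError(SmglycError):
    """Too few complete rows to fit the requested model (n <= p)."""


class ModerationUndefinedError(SmglycError):
    """The moderator takes fewer than two distinct values in the data."""


class BootstrapInstabilityError(SmglycError):
    """More than the tolerated fraction of bootstrap resamples were unusable."""

    def __init__(self, n_bad, n_total):
        self.n_bad = n_bad
        self.n_total = n_total
        super().__init__(
            f"bootstrap unstable: {n_bad}/{n_total} resamples had singular designs"
        )
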