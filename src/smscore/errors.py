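"""Exception hierarchy for the SMS pipeline.

Every stage raises a subclass of :class:`SmsError` so callers can catch
pipeline failures without masking programming errors.
"""


class SmsError(Exception):
    """Base class for all smscore errors."""


class ConfigError(SmsError):
    """A configuration value violates its invariant; names the field."""


class SchemaError(SmsError):
    """An input table is missing a required column or has the wrong dtype."""


class RowError(SmsError):
    """One or more rows of an input table are malformed.

    Carries ``rows``: a list of (line_number, reason) pairs.
    """

    def __init__(self, message: str, rows=None):
        super().__init__(message)
        self.rows = list(rows or [])


class AggregationError(SmsError):
    """Slice aggregation is impossible (e.g. empty slice set)."""


class ValidationError(SmsError):
    """A value violates a physical or logical invariant (negative area...)."""


class SplitError(SmsError):
    """Train/validation split cannot be formed."""


class DegenerateInputError(SmsError):
    """A statistical routine received an input with no information
    (single-class labels, zero margin, no events...)."""


class ScoringError(SmsError):
    """A patient cannot be scored; names the missing metric or cutpoint."""


class FitError(SmsError):
    """A model fit failed (separation, rank deficiency, non-convergence)."""
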