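"""Exception hierarchy for effiq.

All effiq-raised errors derive from :class:`EffiqError` so callers can catch
pipeline failures without masking programming errors.
"""


class EffiqError(Exception):
    """Base class for all effiq errors."""


class ConfigurationError(EffiqError):
    """A config file or required parameter is missing or malformed."""


class ValidationError(EffiqError, ValueError):
    """An input violates a documented precondition or invariant."""


class EdgeDetectionError(EffiqError):
    """The slanted-edge locator could not find a usable edge."""


class EstimationError(EffiqError):
    """A statistical estimator had insufficient or degenerate input."""


class RangeError(EffiqError):
    """A requested value lies outside the tabulated/supported range."""
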