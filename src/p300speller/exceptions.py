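"""Exception hierarchy for the speller pipeline.

Every stage raises a subclass of :class:`SpellerError` so callers can trap
pipeline failures without masking programming errors.
"""


class SpellerError(Exception):
    """Base class for all pipeline errors."""


class DesignError(SpellerError):
    """Experimental design cannot be constructed (e.g. odd subject count)."""


class DomainError(SpellerError, ValueError):
    """Input outside the valid domain of an operation."""


class NotApplicableError(SpellerError):
    """Operation requested for a condition it does not apply to."""


class ConfigError(SpellerError):
    """Mismatched or invalid configuration objects."""


class AlignmentError(SpellerError):
    """Records that must be synchronized differ in length or rate."""


class DegenerateRegressorError(SpellerError):
    """EOG regressors are collinear; the regression is not identifiable."""


class BoundaryError(SpellerError):
    """Epoch windows extend past the edges of the continuous record."""

    def __init__(self, message, offending_events=None):
        super().__init__(message)
        self.offending_events = list(offending_events or [])


class WindowError(SpellerError):
    """Requested analysis window is empty or outside the epoch grid."""


class RateError(SpellerError):
    """Sampling-rate conversion with a non-integer factor."""


class MontageError(SpellerError):
    """Unknown channel name or wrong channel count."""


class LabelError(SpellerError):
    """Class labels missing or single-class training data."""


class ConditioningError(SpellerError):
    """Covariance matrix numerically singular and shrinkage disabled."""


class CoverageError(SpellerError):
    """A flashing sequence does not cover all matrix units."""


class AliasingError(SpellerError):
    """Sampling rate too low for the requested wavelet frequencies."""


class BookkeepingError(SpellerError):
    """Trial/selection bookkeeping is inconsistent."""


class NoInformationError(SpellerError):
    """A test cannot be computed (e.g. all paired differences tie)."""
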