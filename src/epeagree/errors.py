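"""Exception hierarchy for the epeagree pipeline."""


class EpeAgreeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EpeAgreeError):
    """A configuration value is invalid; the message names the field."""


class ThresholdUndefinedError(EpeAgreeError):
    """A percentile threshold was requested for a series with no wet days."""


class InterpolationError(EpeAgreeError):
    """No operating station was available to interpolate from on some day."""


class AlignmentError(EpeAgreeError):
    """Two series or matrices do not share the same date index or unit set."""


class CollinearityError(EpeAgreeError):
    """A regression design matrix is rank-deficient."""
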