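"""Exception types shared across the pipeline stages."""


class CCSplitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CCSplitError):
    """Invalid simulation or scoring configuration."""


class InputError(CCSplitError):
    """Malformed or incomplete input data (e.g. a missing channel)."""


class CalibrationError(CCSplitError):
    """Physical pixel size unavailable and not overridden."""


class EmptySampleError(CCSplitError):
    """A sample with zero included cells cannot be scored."""


class PairingError(CCSplitError):
    """Vehicle/treated records do not belong to the same sample."""


class NormalizationError(CCSplitError):
    """A gel lacks the internal-standard lane."""


class UndefinedResponseError(CCSplitError):
    """A ratio denominator needed for a response statistic is zero."""


class InsufficientDataError(CCSplitError):
    """Too few subjects/pairs/groups for the requested statistic."""


class UndefinedCorrelationError(CCSplitError):
    """Correlation undefined (constant input vector)."""
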