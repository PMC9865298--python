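"""Exception hierarchy for the posture-recognition pipeline.

Every stage raises a subclass of :class:`PostureKitError` so callers (and the
CLI exit-code mapping) can distinguish input-format problems, configuration
mistakes, and calibration failures.
"""


class PostureKitError(Exception):
    """Base class for all errors raised by posturekit."""


class FormatError(PostureKitError):
    """Malformed input file (missing column, unparsable value)."""


class ValidationError(PostureKitError):
    """Input data violates a contract (non-monotone timestamps, NaNs, ...)."""


class ConfigurationError(PostureKitError):
    """Invalid parameter combination (cutoff >= Nyquist, k > n, empty grid)."""


class CalibrationError(PostureKitError):
    """Standing-pose calibration check failed; message names the condition."""


class SignalLossError(PostureKitError):
    """Acceleration magnitude too small to define an orientation (free fall
    or sensor disconnection)."""


class InsufficientDataError(PostureKitError):
    """Not enough samples for the requested operation."""


class SchemaError(PostureKitError):
    """Feature-column schema of a matrix does not match a trained model."""


class DegenerateLabelsError(PostureKitError):
    """A supervised operation received fewer than two classes."""


class ModelIOError(PostureKitError):
    """Model persistence failure (corrupt file, format-version mismatch)."""
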