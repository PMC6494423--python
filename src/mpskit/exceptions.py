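"""Exception hierarchy for mpskit."""


class MPSKitError(Exception):
    """Base class for all mpskit errors."""


class ParameterError(MPSKitError, ValueError):
    """Invalid generative or analysis parameters."""


class FormatError(MPSKitError, ValueError):
    """Malformed localization table or image file."""


class AxisError(MPSKitError):
    """The axon axis cannot be determined (degenerate point cloud)."""


class ProjectionError(MPSKitError):
    """No localization survives projection onto the axis corridor."""


class DegenerateSegmentError(MPSKitError):
    """A profile segment has zero count variance; its autocorrelation is undefined."""


class ConfigError(MPSKitError, ValueError):
    """Invalid analysis or pipeline configuration."""

    def __init__(self, message, violations=None):
        super().__init__(message)
        self.violations = list(violations) if violations is not None else [message]


class DegenerateThresholdError(MPSKitError):
    """Automatic thresholding failed (constant image)."""


class RegistrationError(MPSKitError):
    """Channel registration found no overlap within the search radius."""
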