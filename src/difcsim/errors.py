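"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A numeric parameter is outside its physical or documented domain."""


class GeometryError(ValueError):
    """A position, separation, or depth falls outside the simulated volume."""


class IncompatibleGridError(ValueError):
    """Two fields do not share a voxel grid and optical-property set."""


class UndefinedMaximumError(ValueError):
    """An all-zero profile or collection has no well-defined maximum."""


class UndefinedRatioError(ValueError):
    """A ratio against a zero background is undefined."""


class SingularInputError(ValueError):
    """A degenerate input (zero distance, zero diameter) was supplied."""


class CalibrationError(RuntimeError):
    """The requested calibration target cannot be reached."""


class ConfigError(ValueError):
    """A run configuration document failed validation."""
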