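"""Exception types shared across the package."""


class HabpopError(Exception):
    """Base class for package errors."""


class InvalidParameterError(HabpopError, ValueError):
    """A model parameter violates its documented domain."""


class ValidationError(HabpopError, ValueError):
    """Input data failed validation (bad rows, out-of-range values)."""


class FormatError(HabpopError, ValueError):
    """A file could not be parsed in the expected format."""


class CalibrationError(HabpopError, RuntimeError):
    """The benchmark calibration could not be computed."""


class UnmappedSpotError(HabpopError, ValueError):
    """A spot falls outside the raster extent or on a no-data cell."""
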