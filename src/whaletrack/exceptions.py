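"""Exception types shared across the package."""


class WhaletrackError(Exception):
    """Base class for package errors."""


class InputError(WhaletrackError, ValueError):
    """Invalid user input (coordinates, file rows, missing artifacts)."""


class ConfigurationError(WhaletrackError, ValueError):
    """Inconsistent configuration (grids too coarse, band mismatches)."""


class FitError(WhaletrackError, ValueError):
    """A model fit failed validation (e.g. non-monotonic travel-time curve)."""


class CalibrationError(WhaletrackError, ValueError):
    """Detector precision calibration is impossible for a station."""
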