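"""Exception hierarchy shared across the package."""


class RhogradError(Exception):
    """Base class for all package-specific errors."""


class DegenerateModelError(RhogradError, ValueError):
    """The reaction model is degenerate (e.g. zero total GAP rate somewhere)."""


class InvalidParameterError(RhogradError, ValueError):
    """A model or geometry parameter is outside its admissible range."""


class CalibrationError(RhogradError, RuntimeError):
    """Shape calibration could not reach the requested summary-statistic targets."""


class FitError(RhogradError, RuntimeError):
    """A least-squares fit failed to converge or its domain is invalid."""


class DegenerateNormalizationError(RhogradError, ValueError):
    """Profile normalization is undefined (constant profile)."""


class GeometryError(RhogradError, ValueError):
    """A linescan or mask operation leaves the image domain."""


class SegmentationError(RhogradError, RuntimeError):
    """Cell segmentation failed (empty mask or ambiguous dominant cell)."""


class ConfigError(RhogradError, ValueError):
    """A run configuration is invalid."""
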