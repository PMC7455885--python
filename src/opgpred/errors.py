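"""Exception hierarchy for the pipeline."""


class OpgPredError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OpgPredError):
    """A configuration value is missing or invalid; the message names the field."""


class GeometryError(OpgPredError):
    """A geometric precondition is violated (off-grid path, mismatched grids, empty ROI)."""


class EmptyRegionError(OpgPredError):
    """A region mask with no true voxels was passed to a feature operator."""


class DegenerateScaleError(OpgPredError):
    """Histogram matching cannot determine a scale (constant source volume)."""


class UndefinedRatioError(OpgPredError):
    """A ratio with zero denominator was requested (tortuosity with zero perimeter)."""


class InsufficientDataError(OpgPredError):
    """Too few samples or classes for the requested statistical operation."""


class SchemaError(OpgPredError):
    """Feature tables with inconsistent column schemas cannot be assembled."""
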