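"""Exception hierarchy for the segmentation pipeline."""


class VesselSegError(Exception):
    """Base class for all package errors."""


class ConfigurationError(VesselSegError):
    """A configuration value violates its documented constraints."""


class ParameterError(VesselSegError):
    """An operation argument is outside its valid range."""


class ShapeError(VesselSegError):
    """Images participating in one operation have incompatible shapes."""


class ChannelError(VesselSegError):
    """A color operation received an image without the expected channels."""


class DegenerateHistogramError(VesselSegError):
    """A histogram has too few occupied bins for the requested thresholds."""


class MaskExtractionError(VesselSegError):
    """Field-of-view extraction found no usable foreground."""


class StageError(VesselSegError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
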