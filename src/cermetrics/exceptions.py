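"""Exception hierarchy for the CER measurement pipeline."""


class CermetricsError(Exception):
    """Base class for all package errors."""


class ValidationError(CermetricsError, ValueError):
    """An input violated a documented precondition or invariant."""


class SpecValidationError(ValidationError):
    """A synthetic eye specification violated one of its invariants."""


class MaskShapeError(ValidationError):
    """Segmentation mask rasters do not share a single shape."""


class NonBinaryMaskError(ValidationError):
    """A mask raster contains values other than the binary encoding."""


class MaskContainmentError(ValidationError):
    """Mask containment invariants (pupil within iris, fissure superset) violated."""


class NoIrisError(CermetricsError):
    """No iris-scale circle could be located in the input."""


class EmptyMaskError(ValidationError):
    """A constructed mask is empty (e.g. disc entirely outside the image)."""


class DegenerateVarianceError(CermetricsError):
    """A statistic is undefined because the relevant variance is zero."""


class PipelineError(CermetricsError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
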