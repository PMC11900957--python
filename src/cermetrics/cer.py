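"""Corneal exposure ratio (CER) from segmentation masks and a detected iris.

The CER is the proportion of the full corneal disc (the limbal circle)
that lies inside the palpebral-fissure aperture:

    CER = 100 × |full_iris ∧ exposed_eye| / |full_iris|

where the full-iris Boolean mask sets every pixel within the iris radius
to True and the exposed-cornea mask is the logical AND of that disc with
the exposed-eye mask.  Pixels are counted by centre inclusion with no
partial-pixel weighting.  The denominator is the full disc including the
pupil region — the cornea overlies both iris and pupil — so pupil pixels
inside the aperture count as exposed cornea.

Pixel measurements convert to millimetres through the interlimbal
distance (horizontal white-to-white corneal diameter), taken as 11.7 mm:
``mm_per_px = interlimbal_mm / (2 × iris_radius_px)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyMaskError, PipelineError, ValidationError
from .hough import DetectedCircle, HoughConfig, locate_pupil_iris
from .masks import SegmentationMasks
from .segmentation import Segmenter, segment_reference
from .synthetic import INTERLIMBAL_MM


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre scale anchored on the interlimbal distance."""

    interlimbal_mm: float
    mm_per_px: float


@dataclass(frozen=True)
class CERResult:
    """Exposed-cornea measurement for one eye.

    ``cer_percent`` is kept at full precision internally; rendering
    rounds to two decimals.
    """

    exposed_cornea_px: int
    full_iris_px: int
    cer_percent: float
    iris_circle: DetectedCircle
    pupil_circle: DetectedCircle | None = None
    mm_per_px: float | None = None

    def __str__(self) -> str:
        return f"CER {self.cer_percent:.2f}% ({self.exposed_cornea_px}/{self.full_iris_px} px)"


def full_iris_mask(iris: DetectedCircle, shape: tuple[int, int]) -> np.ndarray:
    """Boolean disc: pixel (x, y) is True iff (x−cx)² + (y−cy)² ≤ r²."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    disc = (xs - iris.center_x) ** 2 + (ys - iris.center_y) ** 2 <= iris.radius**2
    if not disc.any():
        raise EmptyMaskError("iris disc lies entirely outside the image")
    return disc


def compute_cer(masks: SegmentationMasks, iris: DetectedCircle) -> CERResult:
    """Logical-AND CER: full iris disc intersected with the exposed-eye mask."""
    masks.validate()
    disc = full_iris_mask(iris, masks.shape)
    cornea = disc & masks.exposed_eye
    full_px = int(disc.sum())
    exposed_px = int(cornea.sum())
    return CERResult(
        exposed_cornea_px=exposed_px,
        full_iris_px=full_px,
        cer_percent=100.0 * exposed_px / full_px,
        iris_circle=iris,
    )


def calibrate(iris: DetectedCircle, interlimbal_mm: float = INTERLIMBAL_MM) -> Calibration:
    """Millimetres per pixel from the interlimbal (white-to-white) diameter."""
    if iris.radius <= 0:
        raise ValidationError("iris radius must be positive for calibration")
    if interlimbal_mm <= 0:
        raise ValidationError("interlimbal_mm must be positive")
    return Calibration(interlimbal_mm=interlimbal_mm, mm_per_px=interlimbal_mm / (2.0 * iris.radius))


def measure_eye(
    image_or_masks: np.ndarray | SegmentationMasks,
    config: HoughConfig | None = None,
    palette: dict[str, int] | None = None,
    segmenter: Segmenter | None = None,
    interlimbal_mm: float = INTERLIMBAL_MM,
) -> CERResult:
    """Full measurement pipeline for one eye.

    Accepts either a grayscale image (segmented with ``segmenter`` or the
    nearest-palette reference segmenter) or precomputed masks; then
    locates the pupil and iris circles and computes the CER with mm
    calibration attached.  Deterministic: identical input and
    configuration give a bit-identical result.  Stage failures are
    re-raised as :class:`PipelineError` naming the stage.
    """
    if isinstance(image_or_masks, SegmentationMasks):
        masks = image_or_masks.validate()
    else:
        try:
            if segmenter is not None:
                masks = segmenter(image_or_masks)
            else:
                masks = segment_reference(image_or_masks, palette)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("segmentation", str(exc)) from exc

    try:
        pupil, iris = locate_pupil_iris(masks, config)
    except Exception as exc:
        raise PipelineError("circle_detection", str(exc)) from exc

    try:
        result = compute_cer(masks, iris)
        cal = calibrate(iris, interlimbal_mm)
    except Exception as exc:
        raise PipelineError("cer", str(exc)) from exc
    return CERResult(
        exposed_cornea_px=result.exposed_cornea_px,
        full_iris_px=result.full_iris_px,
        cer_percent=result.cer_percent,
        iris_circle=iris,
        pupil_circle=pupil,
        mm_per_px=cal.mm_per_px,
    )
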