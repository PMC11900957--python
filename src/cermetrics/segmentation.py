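"""Segmentation of eye images into per-class binary masks.

Production deployments of CER measurement sit on top of a trained
semantic-segmentation network; this module defines the backend contract
(any callable mapping a grayscale image to :class:`SegmentationMasks`)
and ships a classical nearest-palette reference segmenter that is exact
on synthetic images whose tissue intensities come from a known palette.
The exposed-eye (palpebral fissure) mask is refined as the union of all
within-fissure classes: visible iris, pupil and sclera.
"""

from __future__ import annotations

from typing import Callable, Protocol

import numpy as np

from .exceptions import ValidationError
from .masks import SegmentationMasks
from .synthetic import DEFAULT_PALETTE

#: Contract for a pluggable segmentation backend (e.g. a trained
#: encoder-decoder network): grayscale image in, validated masks out.
Segmenter = Callable[[np.ndarray], SegmentationMasks]

_CLASS_ORDER = ("skin", "sclera", "iris", "pupil")


def segment_reference(image: np.ndarray, palette: dict[str, int] | None = None) -> SegmentationMasks:
    """Nearest-palette-class segmentation of a single-channel image.

    Each pixel is assigned to the tissue class whose nominal intensity is
    closest (ties resolved in the fixed order skin, sclera, iris, pupil).
    Masks are then assembled with the pupil region counted as iris, and
    ``exposed_eye`` as the union of iris, pupil and sclera pixels.
    """
    if image.ndim != 2:
        raise ValidationError(
            f"expected a single-channel image, got shape {image.shape}; "
            "convert multi-channel input to grayscale first"
        )
    palette = dict(DEFAULT_PALETTE) if palette is None else palette
    values = np.array([palette[c] for c in _CLASS_ORDER], dtype=float)
    # distance to each class intensity; argmin takes the first (fixed-order) class on ties
    dist = np.abs(image.astype(float)[..., None] - values[None, None, :])
    labels = np.argmin(dist, axis=-1)

    pupil = labels == _CLASS_ORDER.index("pupil")
    iris = labels == _CLASS_ORDER.index("iris")
    sclera = labels == _CLASS_ORDER.index("sclera")
    return SegmentationMasks(
        visible_iris=iris | pupil,
        visible_pupil=pupil,
        sclera=sclera,
        exposed_eye=iris | pupil | sclera,
    ).validate()
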