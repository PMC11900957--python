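"""Per-class binary segmentation masks and their file round-trip.

The four classes describe one frontal eye photograph: the visible iris
(including the pupil region), the visible pupil, the sclera, and the
palpebral-fissure aperture (``exposed_eye``).  All rasters are boolean,
share one shape, and use the raster convention: 0-based indices, origin
top-left, y increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import MaskContainmentError, MaskShapeError, NonBinaryMaskError

MASK_CLASSES = ("visible_iris", "visible_pupil", "sclera", "exposed_eye")


@dataclass(frozen=True)
class SegmentationMasks:
    """Aligned per-class binary rasters for one eye image.

    Invariants (checked by :meth:`validate`):

    * all rasters share one ``(height, width)`` shape;
    * ``visible_pupil`` is contained in ``visible_iris``;
    * ``exposed_eye`` contains ``visible_iris`` and ``sclera``.
    """

    visible_iris: np.ndarray
    visible_pupil: np.ndarray
    sclera: np.ndarray
    exposed_eye: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.visible_iris.shape

    def validate(self) -> "SegmentationMasks":
        shapes = {getattr(self, c).shape for c in MASK_CLASSES}
        if len(shapes) != 1:
            raise MaskShapeError(f"masks have differing shapes: {sorted(shapes)}")
        for c in MASK_CLASSES:
            arr = getattr(self, c)
            if arr.dtype != bool:
                raise NonBinaryMaskError(f"mask {c!r} has dtype {arr.dtype}, expected bool")
        if np.any(self.visible_pupil & ~self.visible_iris):
            raise MaskContainmentError("visible_pupil is not contained in visible_iris")
        if np.any((self.visible_iris | self.sclera) & ~self.exposed_eye):
            raise MaskContainmentError(
                "exposed_eye does not contain visible_iris union sclera"
            )
        return self


def write_masks(masks: SegmentationMasks, directory: str | Path, stem: str = "eye") -> dict[str, Path]:
    """Write each class as a single-channel 0/255 PNG; return class → path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for c in MASK_CLASSES:
        arr = (getattr(masks, c).astype(np.uint8)) * 255
        path = directory / f"{stem}_{c}.png"
        Image.fromarray(arr, mode="L").save(path)
        paths[c] = path
    return paths


def load_masks(paths: dict[str, str | Path]) -> SegmentationMasks:
    """Load per-class 0/255 PNGs into validated :class:`SegmentationMasks`.

    ``paths`` maps each class name in :data:`MASK_CLASSES` to a file path.
    Distinct errors are raised for a missing class, non-binary pixel values,
    shape mismatches, and containment violations.
    """
    missing = [c for c in MASK_CLASSES if c not in paths]
    if missing:
        raise MaskShapeError(f"missing mask class(es): {missing}")
    arrays = {}
    for c in MASK_CLASSES:
        with Image.open(paths[c]) as img:
            arr = np.asarray(img.convert("L"))
        values = np.unique(arr)
        if not np.isin(values, (0, 255)).all():
            bad = [int(v) for v in values if v not in (0, 255)]
            raise NonBinaryMaskError(f"mask {c!r} contains non-binary values {bad[:5]}")
        arrays[c] = arr > 0
    return SegmentationMasks(**arrays).validate()
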