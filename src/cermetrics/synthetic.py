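"""Parametric synthetic eye images with analytically known ground truth.

Every downstream stage of the CER pipeline (segmentation, circle
detection, mask intersection) can be tested against these images because
the generator paints exact regions: a circular iris disc with a
concentric pupil, a palpebral-fissure aperture bounded by two parabolic
lid curves, sclera inside the fissure and skin outside.  The true
corneal exposure ratio is obtained by pixel counting on the painted
masks, so it is exact by construction, and the eyelid droop parameter
sweeps it from fully exposed to fully covered.

Geometry convention: 0-based pixel indices, origin top-left, y
increasing downward.  A pixel belongs to a disc iff its centre satisfies
the circle inequality ``(x-cx)**2 + (y-cy)**2 <= r**2``; a pixel belongs
to the aperture iff ``y_u(x) <= y <= y_l(x)`` at its centre.  Masks are
hard binary (no anti-aliasing) so ground truth is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import SpecValidationError
from .masks import SegmentationMasks, write_masks

#: Nominal grayscale intensity per tissue class.  Values are spaced so
#: that moderate additive noise never crosses a nearest-class boundary
#: (minimum gap 55 between sclera and skin).
DEFAULT_PALETTE: dict[str, int] = {"skin": 200, "sclera": 255, "iris": 100, "pupil": 20}

#: Horizontal white-to-white corneal diameter used for mm calibration.
INTERLIMBAL_MM = 11.7


def lid_parabola(apex_x: float, apex_y: float, canthus_dx: float, canthus_y: float) -> tuple[float, float, float]:
    """Coefficients ``(a2, a1, a0)`` of the parabola ``y = a2 x^2 + a1 x + a0``
    with vertex at ``(apex_x, apex_y)`` passing through the canthus points
    ``(apex_x ± canthus_dx, canthus_y)``."""
    k = (canthus_y - apex_y) / canthus_dx**2
    return (k, -2.0 * k * apex_x, apex_y + k * apex_x**2)


@dataclass(frozen=True)
class EyeSpec:
    """Full parametric description of one synthetic eye image.

    ``upper_lid`` / ``lower_lid`` are parabola coefficients ``(a2, a1, a0)``
    for the lid-margin curves ``y_u(x)`` and ``y_l(x)``; the aperture is the
    pixel set with ``y_u(x) <= y <= y_l(x)``.  An upper curve everywhere
    below the lower one describes a closed eye (empty aperture), which is a
    valid state, not an error.
    """

    image_width: int = 256
    image_height: int = 256
    iris_center: tuple[float, float] = (128.0, 128.0)
    iris_radius: float = 58.5
    pupil_radius: float = 23.4
    upper_lid: tuple[float, float, float] = lid_parabola(128.0, 69.5, 81.9, 128.0)
    lower_lid: tuple[float, float, float] = lid_parabola(128.0, 183.5, 81.9, 128.0)
    palette: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> "EyeSpec":
        cx, cy = self.iris_center
        r = self.iris_radius
        if r <= 0:
            raise SpecValidationError("iris_radius must be positive")
        if not (0 < self.pupil_radius < r):
            raise SpecValidationError("pupil_radius must lie in (0, iris_radius)")
        if cx - r < 0 or cx + r > self.image_width - 1 or cy - r < 0 or cy + r > self.image_height - 1:
            raise SpecValidationError("iris disc must lie fully inside the image bounds")
        if self.noise_sigma < 0:
            raise SpecValidationError("noise_sigma must be non-negative")
        return self


@dataclass(frozen=True)
class GroundTruth:
    """Exact masks and analytic truth for one generated eye."""

    masks: SegmentationMasks
    true_cer_percent: float
    iris_center: tuple[float, float]
    iris_radius: float
    pupil_radius: float


def _poly_y(coeffs: tuple[float, float, float], x: np.ndarray) -> np.ndarray:
    a2, a1, a0 = coeffs
    return a2 * x**2 + a1 * x + a0


def generate_eye(spec: EyeSpec) -> tuple[np.ndarray, GroundTruth]:
    """Rasterize one eye image and its exact ground-truth masks.

    Painting order: skin everywhere, aperture interior as sclera, visible
    iris (iris disc ∩ aperture), visible pupil.  ``true_cer_percent`` is the
    pixel count of the visible iris divided by the full iris-disc count,
    times 100 — exact on the painted masks by construction.
    """
    spec.validate()
    h, w = spec.image_height, spec.image_width
    cx, cy = spec.iris_center
    ys, xs = np.mgrid[0:h, 0:w]

    dist2 = (xs - cx) ** 2 + (ys - cy) ** 2
    iris_disc = dist2 <= spec.iris_radius**2
    pupil_disc = dist2 <= spec.pupil_radius**2

    x_row = np.arange(w, dtype=float)
    y_u = _poly_y(spec.upper_lid, x_row)
    y_l = _poly_y(spec.lower_lid, x_row)
    aperture = (ys >= y_u[None, :]) & (ys <= y_l[None, :])

    visible_iris = aperture & iris_disc
    visible_pupil = aperture & pupil_disc
    sclera = aperture & ~iris_disc

    masks = SegmentationMasks(
        visible_iris=visible_iris,
        visible_pupil=visible_pupil,
        sclera=sclera,
        exposed_eye=aperture,
    ).validate()

    image = np.full((h, w), spec.palette["skin"], dtype=float)
    image[aperture] = spec.palette["sclera"]
    image[visible_iris] = spec.palette["iris"]
    image[visible_pupil] = spec.palette["pupil"]
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    true_cer = 100.0 * visible_iris.sum() / iris_disc.sum()
    truth = GroundTruth(
        masks=masks,
        true_cer_percent=float(true_cer),
        iris_center=spec.iris_center,
        iris_radius=spec.iris_radius,
        pupil_radius=spec.pupil_radius,
    )
    return image, truth


@dataclass(frozen=True)
class CohortEye:
    """One record of a synthetic cohort: parameters, image and truth."""

    eye_id: str
    droop_mm: float
    spec: EyeSpec
    image: np.ndarray
    truth: GroundTruth


def spec_for_droop(
    droop_mm: float,
    mm_per_px: float = 0.1,
    image_size: int = 256,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> EyeSpec:
    """Eye specification for a given upper-lid droop.

    With the default scale the iris radius is ``11.7 / (2 * mm_per_px)``
    pixels (58.5 px at 0.1 mm/px) so that the interlimbal calibration is
    exact.  At zero droop the upper lid margin rests at the superior
    limbus (CER near 100%); each millimetre of droop lowers the lid apex
    by ``1/mm_per_px`` pixels.  Canthi sit at ``±1.4 r`` horizontally at
    iris-centre height, giving an almond-shaped fissure that never
    occludes the limbus laterally.
    """
    if droop_mm < 0:
        raise SpecValidationError("droop_mm must be non-negative")
    r = INTERLIMBAL_MM / (2.0 * mm_per_px)
    c = image_size / 2.0
    canthus_dx = 1.4 * r
    apex_u = c - r + droop_mm / mm_per_px
    apex_l = c + 0.95 * r
    return EyeSpec(
        image_width=image_size,
        image_height=image_size,
        iris_center=(c, c),
        iris_radius=r,
        pupil_radius=0.4 * r,
        upper_lid=lid_parabola(c, apex_u, canthus_dx, c),
        lower_lid=lid_parabola(c, apex_l, canthus_dx, c),
        noise_sigma=noise_sigma,
        seed=seed,
    )


def generate_cohort(
    n_eyes: int,
    droop_range_mm: tuple[float, float] = (0.0, 8.0),
    mm_per_px: float = 0.1,
    seed: int = 0,
    image_size: int = 256,
    noise_sigma: float = 0.0,
) -> list[CohortEye]:
    """Generate a cohort of eyes with droop drawn uniformly from a range.

    Deterministic for a fixed seed.  The default 0–8 mm range sweeps the
    ground-truth CER from roughly 33% (severe ptosis, lid past the pupil
    centre) to 100% (lid at or above the limbus), covering both severity
    classes of the ≤2 mm / >2 mm clinical grading.
    """
    if n_eyes < 1:
        raise SpecValidationError("n_eyes must be >= 1")
    lo, hi = droop_range_mm
    if lo < 0 or hi < lo:
        raise SpecValidationError("droop_range_mm must satisfy 0 <= lo <= hi")
    rng = np.random.default_rng(seed)
    droops = rng.uniform(lo, hi, size=n_eyes) if hi > lo else np.full(n_eyes, float(lo))
    cohort = []
    for i, droop in enumerate(droops):
        spec = spec_for_droop(
            float(droop),
            mm_per_px=mm_per_px,
            image_size=image_size,
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, truth = generate_eye(spec)
        cohort.append(CohortEye(f"eye{i:03d}", float(droop), spec, image, truth))
    return cohort


def write_cohort(cohort: list[CohortEye], directory: str | Path) -> Path:
    """Write images, masks and a manifest CSV; return the manifest path.

    Manifest columns: eye_id, droop_mm, true_cer, image, and one path
    column per mask class.
    """
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for eye in cohort:
        img_path = directory / "images" / f"{eye.eye_id}.png"
        Image.fromarray(eye.image, mode="L").save(img_path)
        mask_paths = write_masks(eye.truth.masks, directory / "masks", stem=eye.eye_id)
        row = {
            "eye_id": eye.eye_id,
            "droop_mm": eye.droop_mm,
            "true_cer": eye.truth.true_cer_percent,
            "image": str(img_path),
        }
        row.update({f"mask_{c}": str(p) for c, p in mask_paths.items()})
        rows.append(row)
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
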