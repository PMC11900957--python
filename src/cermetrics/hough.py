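"""Circle detection for pupil and iris localization.

The detector follows the classical four-step circular Hough transform:

1. **Edge detection** — hysteresis gradient thresholding (Canny) on
   grayscale images, or morphological boundary extraction on binary
   masks.
2. **Voting** — every edge pixel ``(x, y)`` casts votes for candidate
   centres ``a = x - r cos(θ)``, ``b = y - r sin(θ)`` over θ ∈ [0°, 360°)
   for each candidate radius r.
3. **Peak identification** — accumulator cells whose support reaches a
   threshold proportional to the candidate circumference are kept and
   non-maximum suppression retains locally dominant peaks.
4. **Return values** — centre coordinates, radius and vote support per
   detected circle, sorted by support.

Votes are rounded to integer accumulator cells; ties in peak support are
broken deterministically by (smaller radius, smaller b, smaller a).
Non-maximum suppression measures Euclidean distance in (a, b, r) space
so that concentric circles (pupil inside iris) survive as separate
peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature

from .exceptions import NoIrisError, ValidationError
from .masks import SegmentationMasks


@dataclass(frozen=True)
class DetectedCircle:
    """One detected circular structure.

    ``support`` is the accumulator vote count of the winning cell; a
    value of 0 together with ``synthesized=True`` marks a fallback
    circle that was not actually detected (e.g. a pupil placed at the
    iris centre when no pupil evidence exists).
    """

    center_x: float
    center_y: float
    radius: float
    support: int = 0
    synthesized: bool = False


@dataclass(frozen=True)
class HoughConfig:
    """Numeric parameters of the circular Hough transform.

    ``radius_min``/``radius_max`` default to 5% and 45% of the smaller
    image dimension when left as ``None``; candidate radii are the
    multiples of ``radius_step`` within the bounds.
    ``peak_support_fraction`` sets the acceptance threshold as a
    fraction of the candidate circumference ``2πr``; ``peak_min_support``
    overrides it with an absolute vote count.  The default fraction
    (0.1) accounts for integer-cell rounding spreading the votes of a
    discrete boundary over neighbouring cells — a perfect full circle
    concentrates only ~0.45·2πr votes in its peak cell — while leaving
    headroom to detect circles from a surviving arc of one third.
    """

    radius_min: float | None = None
    radius_max: float | None = None
    radius_step: float = 1.0
    theta_step_deg: float = 1.0
    edge_low: float | None = None
    edge_high: float | None = None
    peak_support_fraction: float = 0.1
    peak_min_support: int | None = None
    nms_min_separation: float = 10.0
    #: pupil radius as a fraction of iris radius used for the fallback
    #: circle when no pupil evidence is present
    pupil_fallback_ratio: float = 0.4

    def validate(self) -> "HoughConfig":
        if self.radius_min is not None and self.radius_max is not None:
            if not (0 < self.radius_min < self.radius_max):
                raise ValidationError("require 0 < radius_min < radius_max")
        if self.radius_step <= 0:
            raise ValidationError("radius_step must be positive")
        if self.theta_step_deg <= 0 or (360.0 / self.theta_step_deg) % 1 != 0:
            raise ValidationError("theta_step_deg must be positive and divide 360")
        return self

    def radius_bounds(self, shape: tuple[int, int]) -> tuple[float, float]:
        m = min(shape)
        rmin = self.radius_min if self.radius_min is not None else 0.05 * m
        rmax = self.radius_max if self.radius_max is not None else 0.45 * m
        if not (0 < rmin < rmax):
            raise ValidationError("require 0 < radius_min < radius_max")
        return rmin, rmax


def detect_edges(image_or_mask: np.ndarray, config: HoughConfig | None = None) -> np.ndarray:
    """Binary edge raster from a grayscale image or binary mask.

    Binary inputs get morphological boundary extraction (mask minus its
    erosion); grayscale inputs go through Canny hysteresis thresholding,
    with thresholds derived from the gradient-magnitude median unless
    set in ``config``.
    """
    if image_or_mask.ndim != 2:
        raise ValidationError(
            f"expected a single-channel raster, got shape {image_or_mask.shape}; "
            "convert multi-channel input to grayscale first"
        )
    config = (config or HoughConfig()).validate()
    arr = image_or_mask
    if arr.dtype == bool or set(np.unique(arr)).issubset({0, 1}):
        mask = arr.astype(bool)
        return mask & ~ndimage.binary_erosion(mask, border_value=0)
    return feature.canny(
        arr.astype(float),
        sigma=1.5,
        low_threshold=config.edge_low,
        high_threshold=config.edge_high,
        use_quantiles=False,
    )


def _vote_radius(
    xs: np.ndarray, ys: np.ndarray, r: float, cos_t: np.ndarray, sin_t: np.ndarray,
    offset: int, acc_w: int, acc_h: int,
) -> np.ndarray:
    """Dense accumulator over centre cells for one candidate radius.

    Votes round half-up (floor(v + 0.5)): unlike round-half-to-even this
    commutes with integer translation, keeping detection equivariant
    under image shifts.
    """
    a = np.floor(xs[:, None] - r * cos_t[None, :] + 0.5).astype(np.int64)
    b = np.floor(ys[:, None] - r * sin_t[None, :] + 0.5).astype(np.int64)
    flat = (b.ravel() + offset) * acc_w + (a.ravel() + offset)
    counts = np.bincount(flat, minlength=acc_h * acc_w)
    return counts.reshape(acc_h, acc_w)


def hough_circles(edges: np.ndarray, config: HoughConfig | None = None) -> list[DetectedCircle]:
    """Detect circles in a binary edge raster; strongest support first.

    Returns an empty list when there are no edge pixels or no
    accumulator cell reaches the support threshold.
    """
    config = (config or HoughConfig()).validate()
    ys, xs = np.nonzero(edges)
    if xs.size == 0:
        return []
    h, w = edges.shape
    rmin, rmax = config.radius_bounds((h, w))
    step = config.radius_step
    radii = np.arange(math.ceil(rmin / step), math.floor(rmax / step) + 1) * step
    if radii.size == 0:
        return []
    thetas = np.deg2rad(np.arange(0.0, 360.0, config.theta_step_deg))
    cos_t, sin_t = np.cos(thetas), np.sin(thetas)

    offset = int(math.ceil(rmax)) + 1
    acc_w, acc_h = w + 2 * offset, h + 2 * offset
    xs_f, ys_f = xs.astype(float), ys.astype(float)

    candidates: list[tuple[int, float, int, int]] = []  # (support, r, b, a)
    for r in radii:
        acc = _vote_radius(xs_f, ys_f, r, cos_t, sin_t, offset, acc_w, acc_h)
        threshold = (
            config.peak_min_support
            if config.peak_min_support is not None
            else config.peak_support_fraction * 2.0 * math.pi * r
        )
        bb, aa = np.nonzero(acc >= max(threshold, 1))
        for b_i, a_i in zip(bb, aa):
            candidates.append((int(acc[b_i, a_i]), float(r), int(b_i) - offset, int(a_i) - offset))

    if not candidates:
        return []
    # sort: support desc, then smaller radius, smaller b, smaller a
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))

    kept: list[tuple[int, float, int, int]] = []
    min_sep2 = config.nms_min_separation**2
    for cand in candidates:
        _, r, b, a = cand
        if all((a - ka) ** 2 + (b - kb) ** 2 + (r - kr) ** 2 >= min_sep2 for _, kr, kb, ka in kept):
            kept.append(cand)
    return [
        DetectedCircle(center_x=float(a), center_y=float(b), radius=r, support=s)
        for s, r, b, a in kept
    ]


def _bbox_radius_window(mask: np.ndarray, margin: float = 5.0) -> tuple[float, float]:
    """Radius search window from the mask's horizontal extent.

    The half-width of the bounding box equals the circle radius whenever
    the structure is not occluded laterally (lids cover from above and
    below), so a narrow window around it is a safe, fast search range.
    """
    cols = np.nonzero(mask.any(axis=0))[0]
    half_width = (cols[-1] - cols[0] + 1) / 2.0
    return max(1.0, half_width - margin), half_width + margin


def locate_pupil_iris(
    masks: SegmentationMasks,
    config: HoughConfig | None = None,
    auto_radius_window: bool = True,
) -> tuple[DetectedCircle, DetectedCircle]:
    """Localize the pupil and iris circles from segmentation masks.

    Edges are taken from the pupil- and iris-mask boundaries.  The iris
    is the best-supported large peak; the pupil the best-supported peak
    with a smaller radius and its centre inside the iris.  With
    ``auto_radius_window`` the radius search range is narrowed around
    each mask's bounding-box half-width (intersected with the configured
    bounds), which is both faster and robust to vertical lid occlusion.

    Raises :class:`NoIrisError` when no iris-scale circle exists.  When
    no usable pupil evidence exists the pupil falls back to a circle at
    the iris centre with ``pupil_fallback_ratio`` of the iris radius,
    marked ``synthesized=True``.
    """
    config = (config or HoughConfig()).validate()
    if not masks.visible_iris.any():
        raise NoIrisError("visible_iris mask is empty")
    rmin, rmax = config.radius_bounds(masks.shape)

    def detect(mask: np.ndarray) -> list[DetectedCircle]:
        lo, hi = (rmin, rmax)
        if auto_radius_window:
            wlo, whi = _bbox_radius_window(mask)
            lo, hi = max(rmin, wlo), min(rmax, whi)
            if lo > hi:
                return []
        sub = HoughConfig(
            radius_min=lo,
            radius_max=hi,
            radius_step=config.radius_step,
            theta_step_deg=config.theta_step_deg,
            peak_support_fraction=config.peak_support_fraction,
            peak_min_support=config.peak_min_support,
            nms_min_separation=config.nms_min_separation,
        )
        edges = detect_edges(mask.astype(bool))
        return hough_circles(edges, sub)

    iris_peaks = detect(masks.visible_iris)
    if not iris_peaks:
        raise NoIrisError("no iris-scale circle found in the visible_iris mask")
    iris = iris_peaks[0]

    pupil: DetectedCircle | None = None
    if masks.visible_pupil.any():
        for peak in detect(masks.visible_pupil):
            inside = (peak.center_x - iris.center_x) ** 2 + (
                peak.center_y - iris.center_y
            ) ** 2 <= iris.radius**2
            if peak.radius < iris.radius and inside:
                pupil = peak
                break
    if pupil is None:
        pupil = DetectedCircle(
            center_x=iris.center_x,
            center_y=iris.center_y,
            radius=config.pupil_fallback_ratio * iris.radius,
            support=0,
            synthesized=True,
        )
    return pupil, iris
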