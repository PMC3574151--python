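"""Region-of-interest handling and automatic Petri-dish detection.

The dish rim is the strongest circle in the image; a Hough circle
transform over a plausible radius range finds it, and the working mask
is a disc of that radius adjusted by a signed pixel margin (the default
of -25 px shrinks safely inside the rim).  Because the dish is
re-detected per image, the mask follows the dish when it shifts between
photographs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.feature import canny
from skimage.measure import block_reduce
from skimage.transform import hough_circle, hough_circle_peaks

from .config import RoiParams

log = logging.getLogger(__name__)

__all__ = ["RoiMask", "full_frame_mask", "detect_dish", "apply_mask",
           "filter_objects"]


@dataclass
class RoiMask:
    mask: np.ndarray  #: bool, same shape as the image
    origin: str       #: "manual", "auto_petri" or "full_frame"

    @property
    def surface(self) -> int:
        return int(self.mask.sum())


def full_frame_mask(shape) -> RoiMask:
    return RoiMask(mask=np.ones(shape, dtype=bool), origin="full_frame")


def _disc_mask(shape, cy, cx, radius) -> np.ndarray:
    yy, xx = np.ogrid[0:shape[0], 0:shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def _canny_quant(img: np.ndarray, sigma: float) -> np.ndarray:
    # quantile thresholds: the rim must stand out against the scene's own
    # gradient distribution, whatever the absolute contrast
    return canny(img / 255.0, sigma=sigma, use_quantiles=True,
                 low_threshold=0.70, high_threshold=0.90)


def _coarse_circle(clamped, factor, lo, hi):
    small = block_reduce(clamped, (factor, factor), np.mean)
    edges = _canny_quant(small, sigma=1.0)
    radii = np.arange(max(lo // factor, 4), max(hi // factor, 5) + 1)
    accum = hough_circle(edges, radii)
    accums, cxs, cys, rads = hough_circle_peaks(accum, radii,
                                                total_num_peaks=1)
    if len(accums) == 0:
        return 0.0, 0, 0, 0
    return (float(accums[0]), int(cxs[0]) * factor, int(cys[0]) * factor,
            int(rads[0]) * factor)


def detect_dish(grey: np.ndarray, margin: int = -25,
                params: RoiParams | None = None) -> RoiMask:
    """Auto-Petri: disc mask from the strongest Hough circle.

    Colonies would both drown the rim in the edge-quantile statistics and
    feed spurious accumulator peaks, so the image is first clamped at its
    median grey level on the side opposite the rim's contrast (dark rims
    on bright-colony plates and vice versa), which removes the colonies
    while leaving the rim untouched.  A coarse Hough search on a 4x
    block-mean image locates the rim; a second pass restricted to edge
    pixels near the coarse circle refines centre and radius.  The mask is
    the detected disc with its radius adjusted by ``margin`` (negative
    shrinks inside the rim).  If no clamping direction yields a circle
    above the accumulator threshold, the full frame is returned with a
    warning.
    """
    params = params or RoiParams()
    grey = np.asarray(grey, dtype=np.float64)
    h, w = grey.shape
    lo = int(params.radius_frac[0] * min(h, w))
    hi = int(params.radius_frac[1] * min(h, w))
    med = float(np.median(grey))

    best = (0.0, 0, 0, 0)
    best_clamped = None
    for clamped in (np.minimum(grey, med), np.maximum(grey, med)):
        cand = _coarse_circle(clamped, 4, lo, hi)
        if cand[0] > best[0]:
            best, best_clamped = cand, clamped
        if best[0] >= params.hough_threshold:
            break
    if best[0] < params.hough_threshold:
        log.warning("auto-petri: no dish found; falling back to full frame")
        return full_frame_mask(grey.shape)

    # refine near the coarse circle; at full resolution for moderate
    # images, at 2x reduction for large ones (the +/-2 px it costs is
    # irrelevant next to the margin)
    rf = 1 if min(h, w) <= 768 else 2
    acc0, cx0, cy0, r0 = best
    ref = (block_reduce(best_clamped, (rf, rf), np.mean) if rf > 1
           else best_clamped)
    edges = _canny_quant(ref, sigma=2.0)
    yy, xx = np.indices(ref.shape)
    d = np.hypot(yy - cy0 / rf, xx - cx0 / rf)
    edges &= np.abs(d - r0 / rf) < 12 / rf
    radii = np.arange(max((r0 - 8) // rf, 4), (r0 + 8) // rf + 1)
    accum = hough_circle(edges, radii)
    accums, cxs, cys, rads = hough_circle_peaks(accum, radii,
                                                total_num_peaks=1)
    if len(accums) == 0:
        return full_frame_mask(grey.shape)
    cy, cx = int(cys[0]) * rf, int(cxs[0]) * rf
    radius = max(int(rads[0]) * rf + int(margin), 1)
    log.info("auto-petri: dish at (%d, %d), mask radius %d px", cx, cy,
             radius)
    return RoiMask(mask=_disc_mask(grey.shape, cy, cx, radius),
                   origin="auto_petri")


def apply_mask(img: np.ndarray, roi: RoiMask, fill=0) -> np.ndarray:
    """Zero (or ``fill``) every pixel outside the ROI."""
    if img.shape[:2] != roi.mask.shape:
        raise ValueError("image and mask dimensions differ")
    if img.ndim == 3:
        return np.where(roi.mask[..., None], img, fill)
    return np.where(roi.mask, img, fill)


def filter_objects(objects, roi: RoiMask):
    """Keep objects whose centre lies inside the mask."""
    kept = []
    for obj in objects:
        y, x = int(round(obj.centroid[0])), int(round(obj.centroid[1]))
        y = min(max(y, 0), roi.mask.shape[0] - 1)
        x = min(max(x, 0), roi.mask.shape[1] - 1)
        if roi.mask[y, x]:
            kept.append(obj)
    return kept
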