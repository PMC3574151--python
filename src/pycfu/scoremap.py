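"""Recursive-threshold score-map.

First pass of the detection: the grey working image is binarised at a
sweep of threshold values; at each threshold every 8-connected component
that passes the particle-filter screen has all its pixels incremented in
a per-pixel vote accumulator.  Pixels that repeatedly belong to a
plausibly circular region over many thresholds collect high scores;
artefacts (rings, arcs, thin cracks, specks) are screened out at every
threshold and score zero.  Finally the score-map itself is thresholded
to yield the object mask for the second pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .config import FilterParams

__all__ = ["ScoreMap", "build_scoremap", "threshold_scoremap",
           "default_thresholds"]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class ScoreMap:
    votes: np.ndarray          #: (H, W) int32, 0 <= votes <= n_thresholds
    n_thresholds: int
    threshold_list: list[int]


def default_thresholds(grey: np.ndarray, stride: int = 1,
                       mask: np.ndarray | None = None) -> list[int]:
    """Every ``stride``-th integer grey level strictly between the ROI's
    min and max — "virtually all possible values" at stride 1."""
    sel = grey[mask] if mask is not None else grey
    if sel.size == 0:
        return []
    lo, hi = int(sel.min()), int(sel.max())
    return list(range(lo + 1, hi, max(int(stride), 1)))


def build_scoremap(grey: np.ndarray, params: FilterParams,
                   thresholds, mask: np.ndarray | None = None) -> ScoreMap:
    """Accumulate screen-passing component votes over a threshold sweep.

    Parameters
    ----------
    grey : (H, W) integer image
    params : FilterParams
        Only the screening constants (``r_min``, ``aspect_screen``,
        ``hollow_screen``) are used here.
    thresholds : sequence of int
        Strictly increasing values in (0, 255).
    mask : bool array, optional
        Pixels outside are ignored at every threshold.

    The per-threshold work is fully vectorised (label + bincount moments),
    but is semantically identical to labelling each binary image and
    calling ``screen_region(compute_features(component), params)`` on
    every component — the naive loop is kept as a test oracle.
    """
    grey = np.asarray(grey)
    thresholds = [int(t) for t in thresholds]
    if len(thresholds) == 0:
        raise ValueError("threshold list is empty")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    if thresholds[0] <= 0 or thresholds[-1] >= 255:
        raise ValueError("thresholds must lie strictly inside (0, 255)")

    h, w = grey.shape
    votes = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.indices((h, w))
    yflat = yy.ravel().astype(np.float64)
    xflat = xx.ravel().astype(np.float64)

    for t in thresholds:
        binary = grey >= t
        if mask is not None:
            binary &= mask
        lbl, n = ndimage.label(binary, structure=_EIGHT)
        if n == 0:
            continue
        flat = lbl.ravel()
        areas = np.bincount(flat, minlength=n + 1)[1:].astype(np.float64)

        sy = np.bincount(flat, weights=yflat, minlength=n + 1)[1:]
        sx = np.bincount(flat, weights=xflat, minlength=n + 1)[1:]
        syy = np.bincount(flat, weights=yflat * yflat, minlength=n + 1)[1:]
        sxx = np.bincount(flat, weights=xflat * xflat, minlength=n + 1)[1:]
        sxy = np.bincount(flat, weights=yflat * xflat, minlength=n + 1)[1:]
        my, mx = sy / areas, sx / areas
        vyy = syy / areas - my * my + 1.0 / 12.0
        vxx = sxx / areas - mx * mx + 1.0 / 12.0
        vxy = sxy / areas - my * mx
        tr = vyy + vxx
        disc = np.sqrt(np.clip(tr * tr / 4.0 - (vyy * vxx - vxy * vxy), 0.0,
                               None))
        lam1 = tr / 2.0 + disc
        lam2 = np.maximum(tr / 2.0 - disc, 1e-12)
        aspect = np.sqrt(lam1 / lam2)

        hollow = np.zeros(n, dtype=np.float64)
        filled = ndimage.binary_fill_holes(binary)
        holes = filled & ~binary
        if holes.any():
            hole_lbl, n_holes = ndimage.label(holes)  # 4-connected holes
            hidx = np.flatnonzero(holes.ravel())      # raster order
            hlab = hole_lbl.ravel()[hidx]
            uniq, first = np.unique(hlab, return_index=True)
            hole_areas = np.bincount(hlab, minlength=n_holes + 1)[1:]
            # the pixel directly above a hole's first (topmost) pixel
            # belongs to the enclosing component
            top = hidx[first]
            owners = lbl.ravel()[top - w]
            hole_per_comp = np.bincount(
                owners, weights=hole_areas[uniq - 1].astype(np.float64),
                minlength=n + 1)[1:]
            hollow = hole_per_comp / (areas + hole_per_comp)

        equiv_radius = np.sqrt(areas / math.pi)
        passed = ((equiv_radius >= params.r_min)
                  & (aspect <= params.aspect_screen)
                  & (hollow <= params.hollow_screen))
        if params.r_max is not None:
            passed &= equiv_radius <= params.screen_rmax_factor * params.r_max
        if passed.any():
            lut = np.zeros(n + 1, dtype=np.int32)
            lut[1:] = passed.astype(np.int32)
            votes += lut[lbl]

    return ScoreMap(votes=votes, n_thresholds=len(thresholds),
                    threshold_list=thresholds)


def threshold_scoremap(sm: ScoreMap, score_threshold) -> np.ndarray:
    """Binarise the vote map: keep pixels with at least the given score.

    ``score_threshold`` may be the string ``"auto"``, in which case Otsu's
    method on the non-zero vote histogram picks the value (the automatic
    rule is implementation-defined).
    """
    if isinstance(score_threshold, str):
        if score_threshold.lower() != "auto":
            raise ValueError("score_threshold must be an int or 'auto'")
        nz = sm.votes[sm.votes > 0]
        if nz.size == 0:
            return np.zeros_like(sm.votes, dtype=bool)
        if np.unique(nz).size == 1:
            return sm.votes > 0
        t = threshold_otsu(nz)
        return sm.votes >= max(int(t), 1)
    score_threshold = int(score_threshold)
    if score_threshold <= 0:
        raise ValueError("score_threshold must be positive")
    if score_threshold > sm.n_thresholds:
        raise ValueError(
            f"score_threshold {score_threshold} exceeds the number of "
            f"thresholds ({sm.n_thresholds}); no pixel can satisfy it")
    return sm.votes >= score_threshold
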