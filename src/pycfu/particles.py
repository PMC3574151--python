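"""Morphological particle filter.

Classifies a connected component as INVALID, SINGLE (one circular
object) or MULTIPLE (a fused cluster) from shape descriptors alone:
area, perimeter, convexity, aspect ratio, hollowness, circularity and
equivalent radius.  This is the decision engine used both while
accumulating the score-map (screening stage only) and in the second
pass (full classification), and again to re-assess watershed fragments.

Not to be confused with sequential Monte-Carlo "particle filters" — the
name here is the blob-analysis sense.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image

from .config import FilterParams

__all__ = ["ParticleClass", "RegionFeatures", "compute_features",
           "screen_region", "classify", "classify_fragment",
           "aspect_ratio_from_moments", "trace_perimeter"]


class ParticleClass(enum.Enum):
    INVALID = "invalid"
    SINGLE = "single"
    MULTIPLE = "multiple"


@dataclass(frozen=True)
class RegionFeatures:
    area: float            #: px^2 (pixel count)
    perimeter: float       #: outer-contour arc length, px
    convex_area: float     #: px^2 of the filled convex hull
    convexity: float       #: area / convex_area, in (0, 1]
    aspect_ratio: float    #: fitted-ellipse major/minor axis ratio, >= 1
    hollowness: float      #: enclosed-hole area / filled area, in [0, 1)
    equiv_radius: float    #: sqrt(area / pi), px
    circularity: float     #: 4*pi*area / perimeter^2


def aspect_ratio_from_moments(ys: np.ndarray, xs: np.ndarray) -> float:
    """Ellipse axis ratio from central second moments.

    A per-axis variance of 1/12 (the variance of a unit pixel) is added
    before taking eigenvalues so one-pixel-wide shapes stay finite.
    """
    y = ys - ys.mean()
    x = xs - xs.mean()
    myy = float(np.mean(y * y)) + 1.0 / 12.0
    mxx = float(np.mean(x * x)) + 1.0 / 12.0
    mxy = float(np.mean(x * y))
    tr, det = myy + mxx, myy * mxx - mxy * mxy
    disc = max(tr * tr / 4.0 - det, 0.0)
    lam1 = tr / 2.0 + math.sqrt(disc)
    lam2 = max(tr / 2.0 - math.sqrt(disc), 1e-12)
    return math.sqrt(lam1 / lam2)


# Moore-neighbour clockwise scan order, starting east.
_NBRS = np.array([(0, 1), (1, 1), (1, 0), (1, -1),
                  (0, -1), (-1, -1), (-1, 0), (-1, 1)])
_STEP_LEN = np.array([1.0, math.sqrt(2)] * 4)


def trace_perimeter(mask: np.ndarray) -> float:
    """Outer-contour length by Moore-neighbour tracing.

    Orthogonal steps count 1, diagonal steps sqrt(2) — this keeps
    circularity stable across disc radii.  Components of one or two
    pixels have no meaningful trace; their perimeter is taken as the
    outline of the pixel squares (4, 6).
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        return 0.0
    if area <= 2:
        return 2.0 * area + 2.0
    padded = np.pad(mask, 1)
    ys, xs = np.nonzero(padded)
    start = (int(ys[0]), int(xs[0]))  # topmost, then leftmost
    offsets = [tuple(o) for o in _NBRS]
    dir_index = {o: i for i, o in enumerate(offsets)}
    length = 0.0
    cur = start
    back_idx = 4  # backtrack points west: start has no foreground west/above
    first_exit = None
    steps = 0
    while steps <= 4 * mask.size + 8:
        steps += 1
        for k in range(1, 9):
            idx = (back_idx + k) % 8
            ny, nx = cur[0] + offsets[idx][0], cur[1] + offsets[idx][1]
            if padded[ny, nx]:
                if cur == start:
                    # Jacob's criterion: stop on re-leaving the start pixel
                    # in the initial direction
                    if first_exit == idx:
                        return length
                    if first_exit is None:
                        first_exit = idx
                length += _STEP_LEN[idx]
                prev = (back_idx + k - 1) % 8  # last background scanned
                py = cur[0] + offsets[prev][0]
                px = cur[1] + offsets[prev][1]
                cur = (ny, nx)
                back_idx = dir_index[(py - ny, px - nx)]
                break
        else:  # no neighbour: isolated pixel (area > 2 makes this unreachable)
            return 4.0
    return length


def _hole_area(mask: np.ndarray) -> float:
    filled = ndimage.binary_fill_holes(mask)
    return float(filled.sum() - mask.sum())


def compute_features(mask: np.ndarray) -> RegionFeatures:
    """Shape descriptors of one 8-connected component given as a mask.

    The mask should be cropped to (or near) the component's bounding box;
    all pixels marked True are treated as one component.
    """
    mask = np.asarray(mask, dtype=bool)
    area = float(mask.sum())
    if area < 1:
        raise ValueError("empty component")
    ys, xs = np.nonzero(mask)
    perimeter = trace_perimeter(mask)
    filled = ndimage.binary_fill_holes(mask)
    filled_area = float(filled.sum())
    hollowness = (filled_area - area) / filled_area
    convex_area = float(convex_hull_image(mask).sum()) if area > 2 else area
    convexity = min(area / convex_area, 1.0) if convex_area > 0 else 1.0
    aspect = aspect_ratio_from_moments(ys.astype(float), xs.astype(float))
    equiv_radius = math.sqrt(area / math.pi)
    circularity = 4.0 * math.pi * area / (perimeter * perimeter)
    return RegionFeatures(area=area, perimeter=perimeter,
                          convex_area=convex_area, convexity=convexity,
                          aspect_ratio=aspect, hollowness=hollowness,
                          equiv_radius=equiv_radius, circularity=circularity)


def screen_region(f: RegionFeatures, p: FilterParams) -> bool:
    """First-stage screen: could this region be made of circular objects?

    Rejects regions that are too small, too elongated, too hollow or far
    too large (``screen_rmax_factor * r_max`` — beyond anything a fused
    cluster of valid colonies produces); used at every threshold of the
    score-map sweep, so it deliberately keeps anything that might be a
    colony or a plausible cluster.  With ``r_max`` unset the size cap is
    inactive.
    """
    if f.equiv_radius < p.r_min or f.aspect_ratio > p.aspect_screen \
            or f.hollowness > p.hollow_screen:
        return False
    if p.r_max is not None \
            and f.equiv_radius > p.screen_rmax_factor * p.r_max:
        return False
    return True


def classify(f: RegionFeatures, p: FilterParams,
             r_max: float | None = None) -> ParticleClass:
    """Second-stage decision: INVALID, SINGLE or MULTIPLE.

    A region showing *single-object evidence* (any of: high circularity;
    high convexity with low aspect ratio; very small equivalent radius)
    is SINGLE provided it passes all confirmation criteria (radius cap,
    convexity floor, hollowness cap), else INVALID.  A region without
    single evidence is MULTIPLE only if all cluster criteria hold
    (bounded hollowness and aspect ratio, convexity floor, and area with
    room for at least two minimal-radius objects), else INVALID.
    """
    if not screen_region(f, p):
        return ParticleClass.INVALID
    r_max = p.resolved_r_max((0, 0)) if r_max is None and p.r_max is None \
        else (r_max if r_max is not None else float(p.r_max))

    # a fused pair can smooth to high circularity or convexity, but its
    # aspect ratio stays >= ~1.5 — so both shape routes require a low
    # aspect ratio as well
    single_evidence = (
        (f.circularity >= p.circ_single and f.aspect_ratio <= p.aspect_single)
        or (f.convexity >= p.conv_single and f.aspect_ratio <= p.aspect_single)
        or f.equiv_radius <= p.small_radius_factor * p.r_min
    )
    if single_evidence:
        confirmed = (f.equiv_radius <= r_max
                     and f.convexity >= p.conv_confirm
                     and f.hollowness <= p.hollow_confirm)
        return ParticleClass.SINGLE if confirmed else ParticleClass.INVALID

    cluster = (f.hollowness <= p.hollow_multi
               and f.aspect_ratio <= p.aspect_multi
               and f.convexity >= p.conv_multi
               and f.area >= p.multi_min_objects * math.pi * p.r_min ** 2)
    return ParticleClass.MULTIPLE if cluster else ParticleClass.INVALID


def classify_fragment(f: RegionFeatures, p: FilterParams,
                      r_max: float | None = None) -> bool:
    """Accept or reject one watershed fragment as a single object.

    A correctly split fragment is a disc with a chord cut off: the cut
    keeps most of the perimeter while removing area, which mechanically
    depresses circularity and convexity below the full-disc bars used by
    :func:`classify`.  Fragments therefore pass with relaxed roundness
    requirements — but the aspect cap stays tight, because a cluster the
    watershed failed to split is elongated, and the size and hollowness
    limits still apply.
    """
    if classify(f, p, r_max) is ParticleClass.SINGLE:
        return True
    r_max = p.resolved_r_max((0, 0)) if r_max is None and p.r_max is None \
        else (r_max if r_max is not None else float(p.r_max))
    return (f.circularity >= p.frag_circ
            and f.convexity >= p.frag_conv
            and f.aspect_ratio <= p.frag_aspect
            and f.hollowness <= p.hollow_confirm
            and p.r_min <= f.equiv_radius <= r_max)
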