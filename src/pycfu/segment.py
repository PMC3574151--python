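"""Second pass: classify score-map components and split fused clusters.

Clusters of touching colonies are segregated with a chamfer distance
transform on a 5x5 neighbourhood (orthogonal step a = 1, diagonal
b = 1.4, knight-move c = 2.1969) followed by a constrained watershed:
regions grow from the distance-map peaks, downhill-or-flat only, and a
region seeded by a peak of value v (its *presumptive radius*) may
neither exceed an area of ``kappa_area * pi * v**2`` nor claim a pixel
whose within-region path distance from the marker reaches
``kappa_dist * v``.  Every fragment produced by the split is re-assessed
by the particle filter before it is accepted.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import FilterParams, SegmentParams
from .particles import ParticleClass, RegionFeatures, classify, \
    classify_fragment, compute_features

__all__ = ["DistanceMap", "Marker", "SegmentedObject", "chamfer_distance",
           "find_markers", "constrained_watershed", "split_and_validate",
           "regularise_mask", "CHAMFER_A", "CHAMFER_B", "CHAMFER_C"]

CHAMFER_A = 1.0      #: orthogonal step
CHAMFER_B = 1.4      #: diagonal step
CHAMFER_C = 2.1969   #: knight-move step (5x5 neighbourhood)

_EIGHT = np.ones((3, 3), dtype=int)

# causal (forward-pass) neighbour offsets, excluding the within-row (0,-1)
# step which is applied by a min-plus prefix scan
_FWD = [(-1, -2, CHAMFER_C), (-1, -1, CHAMFER_B), (-1, 0, CHAMFER_A),
        (-1, 1, CHAMFER_B), (-1, 2, CHAMFER_C),
        (-2, -1, CHAMFER_C), (-2, 1, CHAMFER_C)]


@dataclass
class DistanceMap:
    dist: np.ndarray  #: float64, 0 exactly on background, > 0 on foreground


@dataclass
class Marker:
    label: int
    peak_position: tuple[int, int]  #: (row, col)
    peak_value: float               #: presumptive radius


def _shift_row(row: np.ndarray, dx: int) -> np.ndarray:
    """out[j] = row[j + dx], padded with +inf."""
    out = np.full_like(row, np.inf)
    if dx == 0:
        return row.copy()
    if dx > 0:
        out[:-dx] = row[dx:]
    else:
        out[-dx:] = row[:dx]
    return out


def _scan_left(cand: np.ndarray) -> np.ndarray:
    """Close cand under repeated (0,-1) steps of weight CHAMFER_A."""
    j = np.arange(cand.size, dtype=np.float64)
    with np.errstate(invalid="ignore"):
        acc = np.minimum.accumulate(cand - j * CHAMFER_A)
    return np.minimum(cand, acc + j * CHAMFER_A)


def chamfer_distance(mask: np.ndarray) -> DistanceMap:
    """Two-pass chamfer distance transform of a binary mask.

    Equivalent to the shortest chamfer-weighted path from each foreground
    pixel to the nearest background pixel (pixels beyond the image border
    count as background), with the 5x5 weights a/b/c above.  The two
    raster passes compute this exactly for these weights; a brute-force
    shortest-path search serves as the test oracle.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    # pad with one background ring so the image border acts as background
    d = np.where(np.pad(mask, 2), np.inf, 0.0)

    for i in range(d.shape[0]):
        cand = d[i]
        for dy, dx, wgt in _FWD:
            if i + dy >= 0:
                cand = np.minimum(cand, _shift_row(d[i + dy], dx) + wgt)
        d[i] = _scan_left(cand)
    for i in range(d.shape[0] - 1, -1, -1):
        cand = d[i]
        for dy, dx, wgt in _FWD:
            ii = i - dy  # mirrored offsets
            if ii < d.shape[0]:
                cand = np.minimum(cand, _shift_row(d[ii], -dx) + wgt)
        d[i] = _scan_left(cand[::-1])[::-1]
    return DistanceMap(dist=d[2:2 + h, 2:2 + w])


def find_markers(dm: DistanceMap, nms_radius: float = 2.0,
                 nms_peak_factor: float = 0.7) -> list[Marker]:
    """Local maxima of the distance map, one marker per plateau.

    Adjacent candidate maxima necessarily share one value, so candidate
    pixels are merged into plateaus (8-connected); each plateau yields a
    single marker at the candidate pixel nearest its centroid.  Markers
    are sorted by decreasing peak value (ties by row, column) and a
    marker closer to a higher retained one than ``nms_radius`` — or than
    ``nms_peak_factor`` times that higher peak's presumptive radius — is
    suppressed.  The fixed radius removes double markers from
    digitisation plateaus; the peak-scaled radius removes the spurious
    central maximum of compact clusters (two real colony centres cannot
    be much nearer than one radius).
    """
    dist = dm.dist
    cand = (dist > 0) & (dist >= ndimage.maximum_filter(dist, size=3))
    if not cand.any():
        return []
    lbl, n = ndimage.label(cand, structure=_EIGHT)
    raw: list[tuple[float, int, int]] = []
    for k in range(1, n + 1):
        ys, xs = np.nonzero(lbl == k)
        val = float(dist[ys[0], xs[0]])  # plateau: all candidates equal
        supp = max(nms_radius, nms_peak_factor * val)
        extent = math.hypot(int(ys.max()) - int(ys.min()),
                            int(xs.max()) - int(xs.min()))
        if extent <= supp:
            cy, cx = ys.mean(), xs.mean()
            i = int(np.argmin((ys - cy) ** 2 + (xs - cx) ** 2))
            raw.append((val, int(ys[i]), int(xs[i])))
        else:
            # a plateau longer than the suppression radius is the flat
            # ridge of several equal-sized fused colonies: seed one
            # marker per suppression radius along it
            picked: list[tuple[int, int]] = []
            for y, x in sorted(zip(ys.tolist(), xs.tolist())):
                if all((y - py) ** 2 + (x - px) ** 2 >= supp ** 2
                       for py, px in picked):
                    picked.append((y, x))
                    raw.append((val, y, x))
    raw.sort(key=lambda m: (-m[0], m[1], m[2]))

    kept: list[Marker] = []
    for val, y, x in raw:
        if all((y - m.peak_position[0]) ** 2 + (x - m.peak_position[1]) ** 2
               >= max(nms_radius, nms_peak_factor * m.peak_value) ** 2
               for m in kept):
            kept.append(Marker(label=len(kept) + 1, peak_position=(y, x),
                               peak_value=val))
    return kept


def constrained_watershed(dm: DistanceMap, markers: list[Marker],
                          params: SegmentParams | None = None) -> np.ndarray:
    """Grow labelled regions from the markers over the distance map.

    Growth rules: a marked pixel claims an unmarked foreground neighbour
    of lower-or-equal distance value; a region stops growing once its
    area would exceed ``kappa_area * pi * peak**2`` or the claimed
    pixel's within-region path distance from the marker would reach
    ``kappa_dist * peak``.  Pixels are processed highest-distance first
    (ties by row then column), which makes the result independent of
    marker order.  Unclaimed foreground remains label 0.
    """
    params = params or SegmentParams()
    if not markers:
        raise ValueError("constrained_watershed needs at least one marker")
    dist = dm.dist
    h, w = dist.shape
    labels = np.zeros((h, w), dtype=np.int32)
    geodesic = np.full((h, w), np.inf)
    areas = {m.label: 1 for m in markers}
    area_limit = {m.label: params.kappa_area * math.pi * m.peak_value ** 2
                  for m in markers}
    dist_limit = {m.label: params.kappa_dist * m.peak_value for m in markers}

    heap: list[tuple[float, int, int]] = []
    for m in markers:
        y, x = m.peak_position
        labels[y, x] = m.label
        geodesic[y, x] = 0.0
        heapq.heappush(heap, (-dist[y, x], y, x))

    nbrs = [(-1, -1, CHAMFER_B), (-1, 0, CHAMFER_A), (-1, 1, CHAMFER_B),
            (0, -1, CHAMFER_A), (0, 1, CHAMFER_A),
            (1, -1, CHAMFER_B), (1, 0, CHAMFER_A), (1, 1, CHAMFER_B)]
    while heap:
        negv, y, x = heapq.heappop(heap)
        lab = labels[y, x]
        here = dist[y, x]
        for dy, dx, step in nbrs:
            ny, nx = y + dy, x + dx
            if not (0 <= ny < h and 0 <= nx < w):
                continue
            if labels[ny, nx] != 0 or dist[ny, nx] <= 0:
                continue
            if dist[ny, nx] > here:  # uphill: not claimable from here
                continue
            g = geodesic[y, x] + step
            if g >= dist_limit[lab]:
                continue
            if areas[lab] + 1 > area_limit[lab]:
                break
            labels[ny, nx] = lab
            geodesic[ny, nx] = g
            areas[lab] += 1
            heapq.heappush(heap, (-dist[ny, nx], ny, nx))
    return labels


def regularise_mask(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Majority (binary median) filter of the object mask.

    Pixel noise makes the thresholded score-map's rims ragged, which
    depresses circularity and convexity enough to misclassify clean
    single colonies; a 3x3 majority vote smooths the one-pixel fuzz
    without moving boundaries or bridging the >= 2 px gaps that separate
    distinct objects.
    """
    mask = np.asarray(mask, dtype=bool)
    for _ in range(max(iterations, 0)):
        counts = ndimage.uniform_filter(mask.astype(np.float32), size=3)
        mask = counts > 0.5  # at least 5 of the 9 neighbours set
    return mask


@dataclass
class SegmentedObject:
    """One accepted object, in global image coordinates."""

    centroid: tuple[float, float]     #: (y, x)
    area: float
    perimeter: float
    features: RegionFeatures
    cluster_size: int                 #: objects accepted from the same cluster
    bbox: tuple[int, int, int, int]   #: (y0, x0, y1, x1), half-open
    mask: np.ndarray                  #: bool, shape (y1-y0, x1-x0)


def _accept(local_mask: np.ndarray, oy: int, ox: int,
            feats: RegionFeatures) -> SegmentedObject:
    ys, xs = np.nonzero(local_mask)
    return SegmentedObject(
        centroid=(float(ys.mean()) + oy, float(xs.mean()) + ox),
        area=feats.area, perimeter=feats.perimeter, features=feats,
        cluster_size=1,
        bbox=(oy, ox, oy + local_mask.shape[0], ox + local_mask.shape[1]),
        mask=local_mask)


def split_and_validate(mask: np.ndarray, params: FilterParams,
                       seg_params: SegmentParams | None = None,
                       r_max: float | None = None) -> list[SegmentedObject]:
    """Classify each component of the thresholded score-map and split
    clusters; return the accepted objects.

    SINGLE components are accepted directly; MULTIPLE components go
    through chamfer distance -> markers -> constrained watershed, and
    each fragment is re-assessed — only fragments that classify SINGLE
    survive.  Markers whose presumptive radius is below ``r_min`` cannot
    seed a colony and are dropped (unless no marker is left).  Each
    accepted object records how many siblings, itself included, were
    accepted from its parent cluster.
    """
    seg_params = seg_params or SegmentParams()
    mask = np.asarray(mask, dtype=bool)
    if r_max is None:
        r_max = params.resolved_r_max(mask.shape)
    lbl, n = ndimage.label(mask, structure=_EIGHT)
    objects: list[SegmentedObject] = []
    for k, sl in enumerate(ndimage.find_objects(lbl), start=1):
        if sl is None:
            continue
        local = lbl[sl] == k
        oy, ox = sl[0].start, sl[1].start
        feats = compute_features(local)
        cls = classify(feats, params, r_max)
        if cls is ParticleClass.SINGLE:
            objects.append(_accept(local, oy, ox, feats))
            continue
        if cls is ParticleClass.INVALID:
            continue
        # MULTIPLE: split on the distance map
        dm = chamfer_distance(local)
        markers = find_markers(dm, seg_params.nms_radius,
                               seg_params.nms_peak_factor)
        strong = [m for m in markers if m.peak_value >= params.r_min]
        markers = strong or markers
        if not markers:
            continue
        frag_labels = constrained_watershed(dm, markers, seg_params)
        accepted: list[SegmentedObject] = []
        for m in markers:
            frag = frag_labels == m.label
            if not frag.any():
                continue
            ffeats = compute_features(frag)
            if classify_fragment(ffeats, params, r_max):
                accepted.append(_accept(frag, oy, ox, ffeats))
        for obj in accepted:
            obj.cluster_size = len(accepted)
        objects.extend(accepted)
    return objects
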