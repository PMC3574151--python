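"""Synthetic plate images with exact ground truth.

Every other module of the package is tested against scenes rendered here:
bright or dark circular colonies on a smoothly varying background, fused
colony clusters, and the artefacts that plague real plate photographs —
dish rims, air bubbles trapped in the agar, cracks and dust.  A scene is
fully determined by its :class:`SceneSpec` (including the seed), so any
fixture can be regenerated bit-identically.

Discs are rendered with a one-pixel anti-aliased rim (alpha equal to the
signed distance overshoot, clipped to [0, 1]); hard-edged discs would make
a multi-threshold sweep degenerate because every threshold would select
exactly the same pixel set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as draw_line

__all__ = [
    "Colony",
    "Artefact",
    "SceneSpec",
    "render_scene",
    "translate_image",
    "random_plate",
]


@dataclass
class Colony:
    cx: float
    cy: float
    radius: float
    intensity_offset: float = 90.0
    colour: tuple[int, int, int] = (255, 255, 255)


@dataclass
class Artefact:
    """One non-colony scene element.

    kind must be one of ``bubble``, ``dish_edge``, ``crack``, ``dust``;
    ``params`` holds the geometry for that kind (see the ``_draw_*``
    helpers for the accepted keys and their defaults).
    """

    kind: str
    params: dict = field(default_factory=dict)


@dataclass
class SceneSpec:
    width: int
    height: int
    background_level: float = 120.0
    gradient_amplitude: float = 0.0
    colonies: list[Colony] = field(default_factory=list)
    artefacts: list[Artefact] = field(default_factory=list)
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")
        for c in self.colonies:
            if c.radius < 1:
                raise ValueError("colony radius must be >= 1 px")
            if not (0 <= c.cx < self.width and 0 <= c.cy < self.height):
                raise ValueError("colony centre outside image bounds")


def _background(spec: SceneSpec) -> np.ndarray:
    """Smooth background: constant level plus an optional diagonal ramp."""
    h, w = spec.height, spec.width
    bg = np.full((h, w), spec.background_level, dtype=np.float64)
    if spec.gradient_amplitude:
        yy, xx = np.mgrid[0:h, 0:w]
        ramp = (xx / max(w - 1, 1) + yy / max(h - 1, 1)) / 2.0
        bg += spec.gradient_amplitude * (ramp - 0.5)
    return bg


def _disc_alpha(h, w, cx, cy, radius):
    """Coverage-style alpha of a disc: 1 inside, soft 1-px rim, 0 outside."""
    y0 = max(int(np.floor(cy - radius - 2)), 0)
    y1 = min(int(np.ceil(cy + radius + 3)), h)
    x0 = max(int(np.floor(cx - radius - 2)), 0)
    x1 = min(int(np.ceil(cx + radius + 3)), w)
    if y0 >= y1 or x0 >= x1:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx, yy - cy)
    alpha = np.clip(radius + 0.5 - d, 0.0, 1.0)
    return (slice(y0, y1), slice(x0, x1)), alpha


def _paint_disc(img, bg, cx, cy, radius, offsets):
    """Alpha-composite ``bg + offsets`` (per channel) over the image."""
    hit = _disc_alpha(img.shape[0], img.shape[1], cx, cy, radius)
    if hit is None:
        return
    win, alpha = hit
    a = alpha[..., None]
    target = bg[win][..., None] + np.asarray(offsets, dtype=np.float64)
    img[win] = (1.0 - a) * img[win] + a * target


def _paint_ring(img, bg, cx, cy, radius, width, offset):
    h, w = img.shape[:2]
    pad = radius + width + 2
    y0, y1 = max(int(cy - pad), 0), min(int(cy + pad + 1), h)
    x0, x1 = max(int(cx - pad), 0), min(int(cx + pad + 1), w)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.hypot(xx - cx, yy - cy)
    alpha = np.clip(width / 2.0 + 0.5 - np.abs(d - radius), 0.0, 1.0)
    win = (slice(y0, y1), slice(x0, x1))
    a = alpha[..., None]
    target = np.clip(bg[win] + offset, 0, 255)[..., None]
    img[win] = (1.0 - a) * img[win] + a * target


def _draw_bubble(img, bg, p, rng):
    """Air bubble: a bright ring (agar lensing) around a darker interior."""
    cx, cy = p["cx"], p["cy"]
    radius = p.get("radius", 8.0)
    width = p.get("ring_width", 2.0)
    _paint_disc(img, bg, cx, cy, radius - width / 2.0,
                [-p.get("interior_offset", 25.0)] * 3)
    _paint_ring(img, bg, cx, cy, radius, width, p.get("ring_offset", 60.0))


def _draw_dish_edge(img, bg, p, rng):
    """Petri-dish rim: a dark outer ring with a bright highlight just inside."""
    h, w = img.shape[:2]
    cx = p.get("cx", w / 2.0)
    cy = p.get("cy", h / 2.0)
    radius = p.get("radius", 0.48 * min(w, h))
    width = p.get("width", 3.0)
    _paint_ring(img, bg, cx, cy, radius, width, -p.get("dark_offset", 60.0))
    _paint_ring(img, bg, cx, cy, radius - width - 1, 1.5,
                p.get("bright_offset", 40.0))


def _draw_crack(img, bg, p, rng):
    """Thin dark polyline: a random walk with small angular drift."""
    h, w = img.shape[:2]
    x = p.get("x0", rng.uniform(0.2 * w, 0.8 * w))
    y = p.get("y0", rng.uniform(0.2 * h, 0.8 * h))
    angle = p.get("angle", rng.uniform(0, 2 * np.pi))
    n_seg = int(p.get("segments", 6))
    seg_len = p.get("segment_length", 12.0)
    offset = p.get("offset", -50.0)
    for _ in range(n_seg):
        nx = x + seg_len * np.cos(angle)
        ny = y + seg_len * np.sin(angle)
        rr, cc = draw_line(int(round(y)), int(round(x)),
                           int(round(ny)), int(round(nx)))
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rr, cc = rr[keep], cc[keep]
        img[rr, cc] = np.clip(bg[rr, cc, None] + offset, 0, 255)
        x, y = nx, ny
        angle += rng.uniform(-0.5, 0.5)


def _draw_dust(img, bg, p, rng):
    """Small irregular high-contrast speck (1-4 px across)."""
    h, w = img.shape[:2]
    cx, cy = int(p["cx"]), int(p["cy"])
    n_px = int(p.get("n_pixels", 4))
    offset = p.get("offset", -80.0)
    for _ in range(n_px):
        y = int(np.clip(cy + rng.integers(-1, 2), 0, h - 1))
        x = int(np.clip(cx + rng.integers(-1, 2), 0, w - 1))
        img[y, x] = np.clip(bg[y, x] + offset, 0, 255)


_DRAWERS = {
    "bubble": _draw_bubble,
    "dish_edge": _draw_dish_edge,
    "crack": _draw_crack,
    "dust": _draw_dust,
}

GROUND_TRUTH_COLUMNS = ["id", "kind", "cx", "cy", "radius", "r", "g", "b"]


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a scene to an 8-bit RGB image plus its ground-truth table.

    Returns
    -------
    image : (H, W, 3) uint8 array
    truth : DataFrame with one row per colony (kind ``colony``) and one
        per artefact, columns ``id,kind,cx,cy,radius,r,g,b``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bg = _background(spec)
    img = np.repeat(bg[:, :, None], 3, axis=2)

    rows = []
    for i, c in enumerate(spec.colonies):
        offsets = [c.intensity_offset * ch / 255.0 for ch in c.colour]
        _paint_disc(img, bg, c.cx, c.cy, c.radius, offsets)
        rows.append((i, "colony", c.cx, c.cy, c.radius, *c.colour))
    for j, a in enumerate(spec.artefacts):
        if a.kind not in _DRAWERS:
            raise ValueError(f"unknown artefact kind {a.kind!r}")
        _DRAWERS[a.kind](img, bg, a.params, rng)
        rows.append((len(spec.colonies) + j, a.kind,
                     a.params.get("cx", np.nan), a.params.get("cy", np.nan),
                     a.params.get("radius", np.nan), 0, 0, 0))

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    return img, truth


def translate_image(img: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Shift image content by (dx, dy) pixels; positive dx moves it right.

    A disc centred at (100, 100) ends up at (100 + dx, 100 + dy).  The
    vacated margin is filled by replicating the nearest edge row/column,
    i.e. the local background estimate at the border.
    """
    h, w = img.shape[:2]
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError("shift must be smaller than the image dimensions")
    shift = (dy, dx) if img.ndim == 2 else (dy, dx, 0)
    return ndimage.shift(img, shift, order=0, mode="nearest")


def random_plate(
    n_colonies: int,
    *,
    seed: int,
    width: int = 640,
    height: int = 640,
    radius: float = 5.0,
    radius_jitter: float = 0.8,
    intensity_offset: float = 90.0,
    colour: tuple[int, int, int] = (255, 240, 170),
    pair_fraction: float = 0.2,
    triple_fraction: float = 0.1,
    overlap_gap: tuple[float, float] = (1.45, 1.75),
    triple_gap: tuple[float, float] = (1.6, 1.85),
    n_bubbles: int = 0,
    noise_sigma: float = 3.0,
    gradient_amplitude: float = 15.0,
    dish_edge: bool = True,
    minority: int = 0,
    minority_colour: tuple[int, int, int] = (255, 70, 70),
) -> SceneSpec:
    """Lay out a plausible plate: mostly isolated colonies, a controlled
    share fused into pairs and triples, inside a Petri dish rim.

    ``pair_fraction``/``triple_fraction`` are fractions of *colonies* that
    sit in two- and three-colony clusters; fused neighbours are placed at a
    centre separation drawn from ``overlap_gap`` (in units of the mean
    radius), deep enough to merge into one blob yet shallow enough that the
    distance transform retains one peak per colony.  Placement uses
    rejection sampling on a spatial grid so distinct clusters never touch.
    """
    rng = np.random.default_rng(seed)
    # grow the plate for heavy loads so rejection sampling stays feasible
    needed = int(np.ceil(28.0 * np.sqrt(max(n_colonies, 1)) * radius / 5.0))
    width, height = max(width, needed), max(height, needed)
    dish_r = 0.48 * min(width, height)
    cx0, cy0 = width / 2.0, height / 2.0

    n_pairs = int(round(n_colonies * pair_fraction / 2.0))
    n_triples = int(round(n_colonies * triple_fraction / 3.0))
    n_single = n_colonies - 2 * n_pairs - 3 * n_triples

    placed: list[tuple[float, float, float]] = []  # (cx, cy, clearance)
    cell = 4.0 * radius
    grid: dict[tuple[int, int], list[int]] = {}

    def ok(cx, cy, clearance):
        gx, gy = int(cx // cell), int(cy // cell)
        for ix in range(gx - 2, gx + 3):
            for iy in range(gy - 2, gy + 3):
                for k in grid.get((ix, iy), ()):
                    px, py, pc = placed[k]
                    if np.hypot(px - cx, py - cy) < clearance + pc:
                        return False
        return True

    def commit(cx, cy, clearance):
        placed.append((cx, cy, clearance))
        grid.setdefault((int(cx // cell), int(cy // cell)), []).append(
            len(placed) - 1)

    def sample_centre(clearance):
        max_r = dish_r - 28.0 - clearance
        for _ in range(8000):
            ang = rng.uniform(0, 2 * np.pi)
            rad = max_r * np.sqrt(rng.uniform())
            cx, cy = cx0 + rad * np.cos(ang), cy0 + rad * np.sin(ang)
            if ok(cx, cy, clearance):
                return cx, cy
        raise RuntimeError("could not place colony; plate too crowded")

    colonies: list[Colony] = []

    def draw_radius():
        return radius + rng.uniform(-radius_jitter, radius_jitter)

    def new_colony(cx, cy, r=None):
        colonies.append(Colony(cx, cy, r if r is not None else draw_radius(),
                               intensity_offset, colour))

    def cluster(size):
        # clearance = half-extent of the cluster plus one radius and a gap
        clearance = radius * (1.0 + 0.95 * (size - 1)) + 2.0
        cx, cy = sample_centre(clearance)
        commit(cx, cy, clearance)
        ang = rng.uniform(0, 2 * np.pi)
        # separations scale with the drawn radii, so the stated overlap
        # range holds for every cluster regardless of radius jitter
        rs = [draw_radius() for _ in range(size)]
        gap = overlap_gap if size == 2 else triple_gap
        if size == 2:
            sep = rng.uniform(*gap) * (rs[0] + rs[1]) / 2.0
            dx, dy = sep / 2 * np.cos(ang), sep / 2 * np.sin(ang)
            new_colony(cx - dx, cy - dy, rs[0])
            new_colony(cx + dx, cy + dy, rs[1])
        else:  # chain of three with a slight bend (compact trefoils defeat
            # distance-peak splitting; fused triples on plates are chains)
            bend = rng.uniform(-0.45, 0.45)
            sep01 = rng.uniform(*gap) * (rs[0] + rs[1]) / 2.0
            sep12 = rng.uniform(*gap) * (rs[1] + rs[2]) / 2.0
            new_colony(cx - sep01 * np.cos(ang), cy - sep01 * np.sin(ang),
                       rs[0])
            new_colony(cx, cy, rs[1])
            new_colony(cx + sep12 * np.cos(ang + bend),
                       cy + sep12 * np.sin(ang + bend), rs[2])

    # place the large cluster sites first, then fill in singles
    for _ in range(n_triples):
        cluster(3)
    for _ in range(n_pairs):
        cluster(2)
    for _ in range(n_single):
        cx, cy = sample_centre(radius + 2.0)
        commit(cx, cy, radius + 2.0)
        new_colony(cx, cy)

    # recolour a minority sub-population (contaminant strain)
    idx = rng.permutation(len(colonies))[:minority]
    for i in idx:
        colonies[i].colour = minority_colour

    artefacts = []
    if dish_edge:
        artefacts.append(Artefact("dish_edge",
                                  {"cx": cx0, "cy": cy0, "radius": dish_r}))
    for _ in range(n_bubbles):
        bubble_r = rng.uniform(6.0, 14.0)
        bx, by = sample_centre(bubble_r + 4.0)  # bubbles never swallow colonies
        commit(bx, by, bubble_r + 4.0)
        artefacts.append(Artefact("bubble",
                                  {"cx": bx, "cy": by, "radius": bubble_r}))

    return SceneSpec(width=width, height=height,
                     colonies=colonies, artefacts=artefacts,
                     noise_sigma=noise_sigma,
                     gradient_amplitude=gradient_amplitude,
                     seed=int(rng.integers(0, 2**31 - 1)))
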