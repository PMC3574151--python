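# Methods

`pycfu` counts cell colonies (CFU) and other roughly circular objects in
photographs of agar plates.  The design goal is robustness: dish rims,
air bubbles, cracks and dust must never be counted, colonies touching in
pairs or chains must be separated, and an empty plate must yield zero —
without assuming that foreground objects exist at all.

## Detection model

Detection is a two-pass scheme over a contrast-enhanced grey image.

**Preprocessing.**  Each colour channel is corrected independently: a
large local median filter (square kernel of side `2*r_max + 1`, so no
colony can absorb into the estimate) gives the background; the signed
deviation in the colony-contrast direction (auto-detected from the
dominant deviation sign, overridable) is the foreground; the positive
part of a scale-normalised Laplacian-of-Gaussian response (σ = 1 px,
gain 2) is subtracted to damp one- to two-pixel-wide structures (cracks,
rim highlights) while leaving colony interiors essentially untouched
(discs of radius ≥ 4 px keep ≥ 98 % of their contrast; 1-px lines lose
~70 %).  The three channels are min-max normalised over the region of
interest and averaged into one 8-bit working image.

**First pass — score-map.**  The grey image is binarised at every
integer level between its ROI minimum and maximum (a stride option
trades fidelity for time).  At each threshold, every 8-connected
component is screened by a morphological particle filter, and each pixel
of every screen-passing component gains one vote.  Pixels repeatedly
inside plausibly circular regions collect large scores; artefacts are
screened at every threshold and score zero.  The vote map is then
thresholded (default score 12, the high-definition setting; `auto` uses
Otsu's method on the non-zero vote histogram — the automatic rule is
implementation-defined) and regularised with one 3×3 binary majority
pass, which removes the one-pixel rim fuzz that pixel noise induces
without bridging the ≥ 2 px gaps separating distinct objects.

**Second pass — classification and splitting.**  Each component of the
thresholded score-map is classified *invalid*, *single* or *multiple*
from its shape; clusters are split by a chamfer distance transform and a
constrained watershed, and every fragment is re-assessed before being
accepted.

## The particle filter

Descriptors per component: area, outer-contour perimeter
(Moore-neighbour trace, diagonal steps weighted √2), convexity
(area / convex-hull area), fitted-ellipse aspect ratio (from central
second moments, regularised by the 1/12 px² variance of a single pixel),
hollowness (enclosed-hole area / filled area), equivalent radius
√(area/π) and circularity 4π·area/perimeter².

The decision cascade:

1. **Screen** (also applied at every score-map threshold): reject if
   equivalent radius < `r_min`, aspect ratio > 4, hollowness > 0.35, or
   equivalent radius > 2·`r_max`.  The size cap rejects plate-spanning
   noise or background unions — essential for empty-plate safety — while
   genuine multi-colony clusters (radius ≈ r·√k for k fused colonies)
   stay far below it.
2. **Single evidence** (any one): circularity ≥ 0.90 with aspect ≤ 1.45;
   convexity ≥ 0.95 with aspect ≤ 1.45; equivalent radius ≤ 1.2·`r_min`.
   Both shape routes carry the aspect condition because a fused pair can
   smooth to high circularity or convexity under noise, but its aspect
   ratio never drops below ≈ 1.5.
3. **Single confirmation** (all): equivalent radius ≤ `r_max`, convexity
   ≥ 0.85, hollowness ≤ 0.15.  Evidence without confirmation is invalid.
4. **Cluster confirmation** (all, applied only without single evidence):
   hollowness ≤ 0.25, aspect ≤ 4, convexity ≥ 0.55, and area with room
   for at least two minimal objects (≥ 2π·r_min²) — so a region too
   small for two colonies can never be declared a cluster.

All constants were calibrated on the rendered fixture suite (clean discs
over the radius range, fused dumbbells and chains at the generator's
overlap range, rings, bars, arcs, crack polylines), with the targets of
zero false accepts on artefact fixtures and ≥ 99 % accepts on clean
discs.  They are package choices, exposed in the `[filter]` config
section, not claims about any other implementation.

## Cluster splitting

The distance transform uses the 5×5 chamfer weights a = 1 (orthogonal),
b = 1.4 (diagonal), c = 2.1969 (knight move), computed by the classical
two raster passes; the within-row recurrence is closed by a min-plus
prefix scan so the transform is vectorised row-wise.  A brute-force
Dijkstra search over the same move graph is kept in the tests as an
independent oracle; the two agree exactly on every fixture.

Markers are the local maxima of the distance map.  A compact plateau of
equal-valued maxima merges to the candidate pixel nearest its centroid;
a plateau *longer* than the suppression radius is the flat ridge of
several equal-sized fused colonies and seeds one marker per suppression
radius along it — without this, a fused pair of like-sized colonies
collapses to a single marker because its two centres lie on one
equal-valued ridge.  Two suppressions then run in decreasing-peak order:
maxima within 2 px of a higher one (digitisation plateaus) and maxima
within 0.7× a higher peak's value (double peaks inside one noisy colony;
observed peaks of genuinely distinct colonies drift toward the neck, so
the factor is kept below the geometric ~1 radius bound).  Markers whose
peak — the *presumptive radius* — falls below `r_min` cannot seed a
colony and are dropped when stronger markers exist.

The watershed grows regions from the markers over the distance map,
highest-valued pixels first (ties broken by row then column, making the
result independent of marker order and fully deterministic).  A marked
pixel claims an unmarked foreground neighbour only downhill-or-flat, and
a region seeded by peak value v obeys two caps: area ≤ 1.3·π·v², and
within-region path distance from the marker < 1.25·v.  The area factor
lets a perfect disc be claimed entirely (π·v² plus digitisation slack);
the distance factor is deliberately tight — at 1.5 a marker can wrap
around the neck of a fused pair and strip the far colony's rim, which
was measurable as a systematic undercount before it was reduced.

Fragments are re-assessed before acceptance.  A correct split cuts a
chord through a disc, keeping most of the perimeter while removing area,
which mechanically depresses circularity by ~0.1–0.15 (more when noise
raggedises the contested side of the cut); fragments therefore pass with
relaxed roundness bars (circularity ≥ 0.62, convexity ≥ 0.75, aspect
≤ 1.8, plus the hollowness and radius limits).  The convexity bar is
what keeps artefact pieces out (crack and arc fragments sit below 0.7);
the aspect cap can stay loose because accepting a fragment adds exactly
one object — for counting it is never worse than rejecting it — and the
systematic undercount of strict re-assessment was measurable (~4 % of
true colonies at the full-disc bars).  Accepted objects record how many
siblings their parent cluster produced (`cluster_size`).

## Colour postfilter

Optional.  Each object's colour is summarised by the medians of the
background-subtracted channels over its pixels ("corrected" medians),
normalised by their sum so the representation is illumination-scale
free.  Independent per-channel normals are fitted to the non-split
objects (cluster_size = 1, the detections least likely to be false),
with the standard deviation floored at 10⁻³; fewer than three non-split
objects disables the filter with a warning.  An object is excluded when
its likelihood falls below the user's quantile cutoff; since the
product of normal densities is monotone in the squared z-score sum,
the cutoff is applied as `chi2.sf(Σz², 3) < q`, which makes q = 0 exclude
nothing and never excludes an object at the model mean.  Excluded
objects stay in the detailed output, flagged.

## Dish detection

The working mask is a disc derived from the strongest Hough circle,
radius adjusted by a signed margin (default −25 px).  Colony edges both
drown the rim in edge-quantile statistics and feed spurious accumulator
peaks, so the image is first clamped at its median grey on the side
opposite the rim's contrast — colonies vanish, the rim stays.  A coarse
search on a 4× block-mean image is refined near the winning circle (full
resolution up to 768 px images, 2× above that).  The accumulator
acceptance threshold is 0.55: random edge alignments on structureless
images reach ≈ 0.4, real rims ≥ 0.7.  With no acceptable circle the full
frame is used, with a warning.  Objects are kept if their centre lies
inside the mask, and all processing stages ignore pixels outside it.

## Synthetic scenes

The generator renders anti-aliased discs (1-px coverage rim — hard
edges would make a multi-threshold sweep degenerate) over a background
with a smooth gradient, plus dish rims (dark ring with a bright inner
highlight), bubbles (bright ring, darker interior), cracks (thin dark
random-walk polylines) and dust (1–4 px specks), then Gaussian pixel
noise.  A scene spec's seed fully determines the raster.

`random_plate` lays out study plates: by default 70 % isolated colonies,
20 % in fused pairs (centre separation 1.45–1.75 radii) and 10 % in
fused chains of three (1.6–1.85 radii, bend up to ±26°), radius 5 ± 0.8
px, contrast +90 grey on background 120 with gradient amplitude 15 and
noise σ = 3, inside a rim at 0.48·min(width, height).  Cluster
separations scale with the *drawn* radii of the two neighbours, not the
nominal plate radius, so the stated overlap range holds for every
cluster regardless of radius jitter.  Plates grow
beyond 640² px when the load demands it (side ∝ √n), reaching ≈ 890² at
1000 colonies.  Placement uses grid-accelerated rejection sampling;
cluster sites are placed before singles so dense plates remain feasible.

Separations below ≈ 1.4 radii are not generated: there a fused pair is
geometrically indistinguishable from one disc (circularity ≥ 0.92), and
a compact *triangular* trefoil defeats distance-peak splitting outright
— its global distance maximum sits at the cluster centroid, not at any
colony — which is why fused triples are rendered as chains.  These are
real limitations of the method, shared by its design, not merely of the
generator: passing tests demonstrate robustness to the artefact
inventory and to moderately fused clusters, not to confluent growth,
deep trefoils, lens distortion, specular glare or out-of-focus frames,
none of which the generator emulates.

## Numerical and interface choices

* Tie-breaks everywhere are raster order (row, then column); no stage
  uses randomness, so a batch re-run is byte-identical.
* Thresholds sweep integer grey levels min+1 … max−1 inside the ROI;
  score threshold defaults to 12 and is clamped to the sweep length on
  low-contrast images.
* `r_max` defaults to min(image dimensions)/20 and also sets the median
  kernel; scenes whose colonies approach `r_max` need an explicit
  `median_radius` or `r_max`, since a kernel comparable to the colony
  diameter lets the median absorb the colony.
* Coordinates are 0-based pixel indices, x = column, y = row; object
  positions are pixel-set centroids.
* Summary CSV: `image,count,mask_surface`; detailed CSV:
  `image,mask_surface,x,y,median_r,median_g,median_b,area,perimeter,`
  `cluster_size,excluded`.  Failed images appear with count `NA` and the
  batch continues.

## Problem sizes used in validation

The accuracy study runs 20 plates log-spaced over 10–1000 colonies with
the generator defaults above; robustness studies use 18 colony-free
plates with 0–20 bubbles, five plates re-counted after a 25 px
translation, and artefact-only scenes (rim, cracks, dust).  Oracle
equivalences run on ≤ 32×32 masks (chamfer vs Dijkstra) and a 64×64
scene (vectorised vs naive score-map, pixel-exact).  These sizes are the
package's validation conditions; `scripts/acceptance.py` recomputes all
of them from scratch.
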