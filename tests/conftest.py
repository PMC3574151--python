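import numpy as np
import pytest

from pycfu.config import FilterParams, PipelineConfig
from pycfu.synthetic import Colony, SceneSpec, render_scene


def render_disc_mask(radius, sep=None, n=2, level=165.0, angle=0.0):
    """Binary mask of one disc (sep=None) or a fused row of n discs."""
    size = int(6 * radius + 3 * (sep or 0) * max(n - 1, 1)) + 20
    c = size / 2.0
    if sep is None:
        cols = [Colony(c, c, radius)]
    else:
        offs = np.arange(n) - (n - 1) / 2.0
        cols = [Colony(c + o * sep * np.cos(angle),
                       c + o * sep * np.sin(angle), radius) for o in offs]
    img, _ = render_scene(SceneSpec(size, size, colonies=cols))
    return img[:, :, 0].astype(float) > level


@pytest.fixture
def filter_params():
    return FilterParams()


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def disc_mask():
    return render_disc_mask


def chamfer_oracle(mask):
    """Brute-force chamfer distance: Dijkstra over the 5x5 move graph.

    Independent of the two-pass implementation; treats everything beyond
    the image border as background (like the implementation's padding).
    """
    import heapq

    a, b, c = 1.0, 1.4, 2.1969
    moves = [(0, 1, a), (0, -1, a), (1, 0, a), (-1, 0, a),
             (1, 1, b), (1, -1, b), (-1, 1, b), (-1, -1, b),
             (1, 2, c), (1, -2, c), (-1, 2, c), (-1, -2, c),
             (2, 1, c), (2, -1, c), (-2, 1, c), (-2, -1, c)]
    padded = np.pad(np.asarray(mask, dtype=bool), 2)
    h, w = padded.shape
    dist = np.where(padded, np.inf, 0.0)
    heap = [(0.0, y, x) for y, x in zip(*np.nonzero(~padded))]
    heapq.heapify(heap)
    while heap:
        d, y, x = heapq.heappop(heap)
        if d > dist[y, x]:
            continue
        for dy, dx, wgt in moves:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and d + wgt < dist[ny, nx]:
                dist[ny, nx] = d + wgt
                heapq.heappush(heap, (d + wgt, ny, nx))
    return dist[2:-2, 2:-2]


def scoremap_oracle(grey, params, thresholds, mask=None):
    """Naive score-map: per threshold, label and screen each component."""
    from scipy import ndimage

    from pycfu.particles import compute_features, screen_region

    grey = np.asarray(grey)
    votes = np.zeros(grey.shape, dtype=np.int64)
    for t in thresholds:
        binary = grey >= t
        if mask is not None:
            binary &= mask
        lbl, n = ndimage.label(binary, structure=np.ones((3, 3)))
        for k in range(1, n + 1):
            comp = lbl == k
            if screen_region(compute_features(comp), params):
                votes[comp] += 1
    return votes
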