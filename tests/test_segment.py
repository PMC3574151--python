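"""Chamfer transform, markers, constrained watershed and cluster splitting."""

import math

import numpy as np
import pytest

from pycfu.config import FilterParams, SegmentParams
from pycfu.segment import (chamfer_distance, constrained_watershed,
                           find_markers, regularise_mask, split_and_validate)
from tests.conftest import chamfer_oracle, render_disc_mask


def geodesic_within(region, start, a=1.0, b=1.4):
    """Test-side shortest path from start inside a region (8-connected)."""
    import heapq

    h, w = region.shape
    dist = np.full((h, w), np.inf)
    dist[start] = 0.0
    heap = [(0.0, *start)]
    moves = [(0, 1, a), (0, -1, a), (1, 0, a), (-1, 0, a),
             (1, 1, b), (1, -1, b), (-1, 1, b), (-1, -1, b)]
    while heap:
        d, y, x = heapq.heappop(heap)
        if d > dist[y, x]:
            continue
        for dy, dx, wgt in moves:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and region[ny, nx] \
                    and d + wgt < dist[ny, nx]:
                dist[ny, nx] = d + wgt
                heapq.heappush(heap, (d + wgt, ny, nx))
    return dist


class TestChamfer:
    def test_isolated_pixel_one_orthogonal_step(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        assert chamfer_distance(m).dist[2, 2] == 1.0

    def test_diagonal_nearest_background(self):
        # 3x3 block with orthogonal neighbours removed: centre of a plus
        m = np.zeros((7, 7), dtype=bool)
        m[2:5, 2:5] = True
        d = chamfer_distance(m).dist
        assert d[2, 2] == pytest.approx(1.0)   # corner: orthogonal step out
        assert d[3, 3] == pytest.approx(2.0)   # centre: two orthogonal steps

    def test_background_exactly_zero_foreground_positive(self):
        m = render_disc_mask(9)
        d = chamfer_distance(m).dist
        assert (d[~m] == 0).all()
        assert (d[m] > 0).all()

    @pytest.mark.parametrize("fixture", ["square7", "disc", "dumbbell",
                                         "l_shape", "random"])
    def test_equals_brute_force_shortest_path(self, fixture):
        if fixture == "square7":
            m = np.zeros((11, 11), dtype=bool)
            m[2:9, 2:9] = True
        elif fixture == "disc":
            m = render_disc_mask(6)[:32, :32]
        elif fixture == "dumbbell":
            m = render_disc_mask(6, sep=9)[10:42, 10:42]
        elif fixture == "l_shape":
            m = np.zeros((20, 20), dtype=bool)
            m[3:17, 3:8] = True
            m[12:17, 3:17] = True
        else:
            rng = np.random.default_rng(7)
            m = rng.random((32, 32)) < 0.6
        assert np.allclose(chamfer_distance(m).dist, chamfer_oracle(m))

    def test_lipschitz_in_chamfer_steps(self):
        rng = np.random.default_rng(11)
        m = rng.random((40, 40)) < 0.7
        d = chamfer_distance(m).dist
        assert np.abs(np.diff(d, axis=0)).max() <= 1.0 + 1e-9
        assert np.abs(np.diff(d, axis=1)).max() <= 1.0 + 1e-9


class TestMarkers:
    def test_single_disc_single_marker_at_centre(self):
        m = render_disc_mask(10)
        ys, xs = np.nonzero(m)
        markers = find_markers(chamfer_distance(m))
        assert len(markers) == 1
        y, x = markers[0].peak_position
        assert abs(y - ys.mean()) <= 1.5 and abs(x - xs.mean()) <= 1.5

    def test_dumbbell_two_markers(self):
        m = render_disc_mask(10, sep=30)
        markers = find_markers(chamfer_distance(m))
        assert len(markers) == 2

    def test_flat_zero_map_no_markers(self):
        m = np.zeros((10, 10), dtype=bool)
        assert find_markers(chamfer_distance(m)) == []

    def test_markers_sorted_by_decreasing_peak(self):
        m = render_disc_mask(8, sep=40) | render_disc_mask(8, sep=40)
        markers = find_markers(chamfer_distance(m))
        peaks = [mk.peak_value for mk in markers]
        assert peaks == sorted(peaks, reverse=True)


class TestWatershed:
    def test_single_marker_claims_whole_disc(self):
        m = render_disc_mask(10)
        dm = chamfer_distance(m)
        markers = find_markers(dm)
        labels = constrained_watershed(dm, markers)
        assert ((labels > 0) == m).all()

    def test_dumbbell_split_boundary_in_neck(self):
        m = render_disc_mask(10, sep=15)
        dm = chamfer_distance(m)
        markers = find_markers(dm)
        labels = constrained_watershed(dm, markers)
        assert len(markers) == 2
        # compare against the nearest-marker (Voronoi) partition
        yy, xx = np.indices(m.shape)
        d = [np.hypot(yy - mk.peak_position[0], xx - mk.peak_position[1])
             for mk in markers]
        voronoi = np.where(d[0] <= d[1], markers[0].label, markers[1].label)
        interior = m & (labels > 0) & (np.abs(d[0] - d[1]) > 1.5)
        assert (labels[interior] == voronoi[interior]).all()

    def test_labels_partition_foreground_subset(self):
        m = render_disc_mask(9, sep=14, n=3)
        dm = chamfer_distance(m)
        labels = constrained_watershed(dm, find_markers(dm))
        assert not (labels[~m] > 0).any()

    def test_no_markers_is_an_error(self):
        m = render_disc_mask(8)
        with pytest.raises(ValueError):
            constrained_watershed(chamfer_distance(m), [])

    @pytest.mark.parametrize("sep", [14, 16, 18])
    def test_area_and_distance_limits_hold_post_hoc(self, sep):
        params = SegmentParams()
        m = render_disc_mask(10, sep=sep)
        dm = chamfer_distance(m)
        markers = find_markers(dm, params.nms_radius, params.nms_peak_factor)
        labels = constrained_watershed(dm, markers, params)
        for mk in markers:
            region = labels == mk.label
            if not region.any():
                continue
            assert region.sum() <= \
                params.kappa_area * math.pi * mk.peak_value ** 2 + 1e-9
            geo = geodesic_within(region, mk.peak_position)
            assert geo[region].max() < params.kappa_dist * mk.peak_value

    def test_deterministic(self):
        m = render_disc_mask(9, sep=14)
        dm = chamfer_distance(m)
        markers = find_markers(dm)
        l1 = constrained_watershed(dm, markers)
        l2 = constrained_watershed(dm, markers)
        assert (l1 == l2).all()


class TestSplitAndValidate:
    def test_two_fused_discs_give_two_objects(self, filter_params):
        m = render_disc_mask(8, sep=12)
        objs = split_and_validate(m, filter_params, r_max=30.0)
        assert len(objs) == 2
        assert all(o.cluster_size == 2 for o in objs)

    def test_three_fused_discs_give_three_objects(self, filter_params):
        m = render_disc_mask(8, sep=13, n=3)
        objs = split_and_validate(m, filter_params, r_max=30.0)
        assert len(objs) == 3
        assert all(o.cluster_size == 3 for o in objs)

    def test_clean_disc_accepted_unsplit(self, filter_params):
        m = render_disc_mask(10)
        objs = split_and_validate(m, filter_params, r_max=30.0)
        assert len(objs) == 1
        assert objs[0].cluster_size == 1

    def test_crack_yields_nothing(self, filter_params):
        crack = np.zeros((80, 80), dtype=bool)
        y = 20.0
        for x in range(8, 72):
            y += 0.4 * np.sin(x / 6.0)
            crack[int(y):int(y) + 2, x] = True
        assert split_and_validate(crack, filter_params, r_max=30.0) == []

    def test_centroids_in_global_coordinates(self, filter_params):
        m = np.zeros((90, 120), dtype=bool)
        disc = render_disc_mask(8)
        ys, xs = np.nonzero(disc)
        m[5 + ys - ys.min(), 70 + xs - xs.min()] = True
        objs = split_and_validate(m, filter_params, r_max=30.0)
        assert len(objs) == 1
        y, x = objs[0].centroid
        assert 5 <= y <= 30 and 70 <= x <= 95


def test_regularise_mask_removes_fuzz_keeps_shape():
    m = render_disc_mask(10)
    rng = np.random.default_rng(5)
    noisy = m.copy()
    ys, xs = np.nonzero(~m)
    pick = rng.choice(len(ys), 12, replace=False)
    noisy[ys[pick], xs[pick]] = True  # isolated speckle
    cleaned = regularise_mask(noisy, 1)
    assert (cleaned[ys[pick], xs[pick]] == False).sum() >= 10  # noqa: E712
    inner = chamfer_distance(m).dist > 2
    assert cleaned[inner].all()
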