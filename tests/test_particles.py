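"""Shape descriptors and the particle-filter decision cascade."""

import numpy as np
import pytest

from pycfu.config import FilterParams
from pycfu.particles import (ParticleClass, classify, classify_fragment,
                             compute_features, screen_region,
                             trace_perimeter)
from tests.conftest import render_disc_mask


def ring_mask(r_out=15, width=3, size=40):
    yy, xx = np.mgrid[0:size, 0:size]
    d = np.hypot(yy - size / 2, xx - size / 2)
    return np.abs(d - r_out) <= width / 2


class TestFeatures:
    def test_disc_is_round_solid_and_compact(self):
        f = compute_features(render_disc_mask(20))
        assert f.convexity >= 0.98
        assert f.aspect_ratio <= 1.05
        assert f.hollowness == 0.0
        assert f.circularity >= 0.9
        assert abs(f.equiv_radius - 20) <= 1.0

    def test_bar_is_elongated(self):
        bar = np.zeros((50, 50), dtype=bool)
        bar[20:23, 5:45] = True
        f = compute_features(bar)
        assert f.aspect_ratio >= 10

    def test_punched_hole_sets_hollowness(self):
        disc = render_disc_mask(12)
        ys, xs = np.nonzero(disc)
        cy, cx = int(ys.mean()), int(xs.mean())
        punched = disc.copy()
        hole = np.zeros_like(disc)
        hole[cy - 1:cy + 2, cx - 1:cx + 2] = True  # 9-px hole
        punched &= ~hole
        f = compute_features(punched)
        assert f.hollowness == pytest.approx(9.0 / (f.area + 9.0))

    def test_perimeter_scales_linearly_with_radius(self):
        peris = [compute_features(render_disc_mask(r)).perimeter
                 for r in (8, 16, 32)]
        assert peris[1] / peris[0] == pytest.approx(2.0, rel=0.08)
        assert peris[2] / peris[1] == pytest.approx(2.0, rel=0.08)

    def test_perimeter_of_square(self):
        sq = np.zeros((20, 20), dtype=bool)
        sq[5:15, 5:15] = True
        assert trace_perimeter(sq) == pytest.approx(36.0)  # 4 * (10 - 1)

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            compute_features(np.zeros((5, 5), dtype=bool))


class TestScreen:
    def test_disc_below_minimal_radius_fails(self, filter_params):
        small = render_disc_mask(filter_params.r_min / 2)
        assert not screen_region(compute_features(small), filter_params)

    def test_clean_disc_passes(self, filter_params):
        disc = render_disc_mask(2 * filter_params.r_min)
        assert screen_region(compute_features(disc), filter_params)

    def test_hollow_ring_fails(self, filter_params):
        f = compute_features(ring_mask())
        assert f.hollowness > 0.5
        assert not screen_region(f, filter_params)

    def test_thin_bar_fails(self, filter_params):
        bar = np.zeros((60, 60), dtype=bool)
        bar[28:31, 5:55] = True
        assert not screen_region(compute_features(bar), filter_params)


class TestClassify:
    R_MAX = 30.0

    def test_clean_discs_classify_single_across_radii(self, filter_params):
        for r in np.arange(filter_params.r_min + 1, self.R_MAX - 2, 2.0):
            f = compute_features(render_disc_mask(r))
            assert classify(f, filter_params, self.R_MAX) \
                is ParticleClass.SINGLE, f"radius {r}"

    def test_overlapping_pair_classifies_multiple(self, filter_params):
        dumbbell = render_disc_mask(10, sep=15)  # centres 1.5 r apart
        f = compute_features(dumbbell)
        assert classify(f, filter_params, self.R_MAX) \
            is ParticleClass.MULTIPLE

    def test_crack_fragment_is_invalid(self, filter_params):
        crack = np.zeros((60, 60), dtype=bool)
        for i in range(40):  # bent thin polyline
            crack[20 + i // 3, 8 + i] = True
            crack[21 + i // 3, 8 + i] = True
        f = compute_features(crack)
        assert classify(f, filter_params, self.R_MAX) \
            is ParticleClass.INVALID

    def test_oversized_disc_is_invalid(self, filter_params):
        f = compute_features(render_disc_mask(25))
        assert classify(f, filter_params, r_max=15.0) \
            is ParticleClass.INVALID

    def test_small_region_never_multiple(self, filter_params):
        # area below two minimal objects cannot be a cluster
        rng = np.random.default_rng(0)
        limit = 2 * np.pi * filter_params.r_min ** 2
        for _ in range(50):
            blob = np.zeros((20, 20), dtype=bool)
            ys = rng.integers(4, 16, 12)
            xs = rng.integers(4, 16, 12)
            blob[ys, xs] = True
            blob[ys + 1, xs] = True
            f = compute_features(blob)
            if f.area < limit:
                assert classify(f, filter_params, self.R_MAX) \
                    is not ParticleClass.MULTIPLE

    def test_identical_features_identical_class(self, filter_params):
        f = compute_features(render_disc_mask(8))
        assert classify(f, filter_params, self.R_MAX) \
            == classify(f, filter_params, self.R_MAX)


class TestFragment:
    def test_half_disc_fragment_accepted(self, filter_params):
        disc = render_disc_mask(8)
        half = disc.copy()
        ys, xs = np.nonzero(disc)
        half[:, :int(xs.mean()) - 5] = False  # chord cut
        assert classify_fragment(compute_features(half), filter_params, 30.0)

    def test_elongated_fragment_rejected(self, filter_params):
        pair = render_disc_mask(8, sep=13)  # unsplit dumbbell
        assert not classify_fragment(compute_features(pair),
                                     filter_params, 30.0)
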