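"""Background estimation, LoG enhancement and channel merging."""

import numpy as np
import pytest

from pycfu.preprocess import (detect_polarity, enhance_channel,
                              estimate_background, foreground_deviation,
                              merge_channels, preprocess_image)
from pycfu.synthetic import Colony, SceneSpec, render_scene


class TestBackground:
    def test_uniform_channel_gives_flat_background_zero_foreground(self):
        ch = np.full((60, 60), 100.0)
        bg = estimate_background(ch, radius=10)
        assert (bg == 100).all()
        assert (foreground_deviation(ch, bg) == 0).all()

    def test_disc_on_ramp_recovered_by_subtraction(self):
        # known synthetic background: linear ramp; one +50 disc of r=10
        yy, xx = np.mgrid[0:96, 0:96]
        ramp = 60.0 + 40.0 * xx / 95.0
        d = np.hypot(yy - 48, xx - 48)
        ch = ramp + 50.0 * (d <= 10)
        fg = foreground_deviation(ch, estimate_background(ch, radius=25))
        border = np.zeros_like(d, dtype=bool)
        border[12:-12, 12:-12] = True  # kernel edge effects excluded
        inside = d <= 7                # rim pixels excluded
        outside = (d >= 14) & border
        assert np.abs(fg[inside] - 50).max() <= 3
        assert np.abs(fg[outside]).max() <= 3

    def test_kernel_larger_than_image_raises(self):
        with pytest.raises(ValueError, match="at least"):
            estimate_background(np.zeros((20, 20)), radius=25)


class TestEnhance:
    def test_zero_in_zero_out(self):
        assert (enhance_channel(np.zeros((32, 32))) == 0).all()

    def test_plateau_interior_unchanged(self):
        # LoG of a wide plateau is ~0 in the interior: brute-force check
        fg = np.zeros((64, 64))
        fg[16:48, 16:48] = 80.0
        out = enhance_channel(fg)
        assert np.abs(out[24:40, 24:40] - 80.0).max() <= 1.0

    def test_output_never_exceeds_input(self):
        rng = np.random.default_rng(0)
        fg = rng.uniform(0, 100, (40, 40))
        assert (enhance_channel(fg) <= fg + 1e-9).all()

    def test_thin_line_suppressed_more_than_disc(self):
        line = np.zeros((40, 40))
        line[20, 5:35] = 90.0
        disc_img, _ = render_scene(SceneSpec(
            48, 48, background_level=0, colonies=[Colony(24, 24, 6, 90)]))
        disc = disc_img[:, :, 0].astype(float)
        line_keep = enhance_channel(line).max() / 90.0
        disc_keep = enhance_channel(disc).max() / disc.max()
        assert line_keep < 0.5 < disc_keep


class TestMerge:
    def test_three_identical_channels_equal_normalised_channel(self):
        rng = np.random.default_rng(1)
        ch = rng.uniform(0, 50, (30, 30))
        grey = merge_channels([ch, ch, ch])
        expected = np.rint((ch - ch.min()) * 255 / (ch.max() - ch.min()))
        assert np.abs(grey.astype(float) - expected).max() <= 1

    def test_constant_channel_contributes_zero_with_warning(self, caplog):
        rng = np.random.default_rng(2)
        ch = rng.uniform(0, 50, (30, 30))
        flat = np.full((30, 30), 7.0)
        with caplog.at_level("WARNING"):
            grey = merge_channels([ch, flat, flat])
        assert "constant" in caplog.text
        # stated rule: mean over all three channels, zero channels included
        expected = merge_channels([ch, ch, ch]).astype(float) / 3.0
        assert np.abs(grey - expected).max() <= 1

    def test_single_channel_convenience_path(self):
        ch = np.linspace(0, 10, 100).reshape(10, 10)
        grey = merge_channels([ch])
        assert grey.min() == 0 and grey.max() == 255


class TestPipelineProperties:
    def test_constant_offset_invariance(self):
        spec = SceneSpec(96, 96, background_level=80,
                         colonies=[Colony(48, 48, 8, 70)])
        img, _ = render_scene(spec)
        grey1, _ = preprocess_image(img, r_max=12)
        shifted = np.clip(img.astype(int) + 40, 0, 255).astype(np.uint8)
        grey2, _ = preprocess_image(shifted, r_max=12)
        assert np.abs(grey1.astype(int) - grey2.astype(int)).max() <= 2

    def test_output_shape_matches_input(self):
        img, _ = render_scene(SceneSpec(70, 50, colonies=[Colony(25, 25, 5)]))
        grey, fgs = preprocess_image(img, r_max=8)
        assert grey.shape == (50, 70)
        assert len(fgs) == 3 and fgs[0].shape == (50, 70)

    def test_polarity_auto_detects_dark_colonies(self):
        spec = SceneSpec(96, 96, background_level=160,
                         colonies=[Colony(48, 48, 9, -80)])
        img, _ = render_scene(spec)
        grey, _ = preprocess_image(img, r_max=12)
        assert grey[48, 48] > 200  # dark colony surfaced as bright foreground

    def test_detect_polarity_direction(self):
        ch = np.full((40, 40), 100.0)
        bright = ch.copy(); bright[10:20, 10:20] = 160
        dark = ch.copy(); dark[10:20, 10:20] = 40
        bg = [np.full((40, 40), 100.0)]
        assert detect_polarity([bright], bg) == "bright"
        assert detect_polarity([dark], bg) == "dark"
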