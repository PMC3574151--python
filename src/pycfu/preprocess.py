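"""Colour image to contrast-enhanced grey image.

Each channel is corrected independently: a large local median filter
estimates the slowly varying background, the signed deviation in the
colony-contrast direction becomes the foreground, and the positive part
of a Laplacian-of-Gaussian response is subtracted from the foreground to
sharpen object rims and damp thin high-curvature structures (cracks,
rim highlights).  The three enhanced channels are min-max normalised and
averaged into one grey-scale working image.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import ndimage
from skimage.filters import rank
from skimage.morphology import footprint_rectangle

log = logging.getLogger(__name__)

__all__ = [
    "estimate_background",
    "foreground_deviation",
    "detect_polarity",
    "enhance_channel",
    "merge_channels",
    "preprocess_image",
]


def estimate_background(channel: np.ndarray, radius: int = 25) -> np.ndarray:
    """Smooth background of one channel by a local median filter.

    The kernel is a ``(2*radius+1)`` square; it must be strictly larger
    than the largest expected colony so that colonies do not absorb into
    the background estimate.

    Raises
    ------
    ValueError
        if the image is smaller than the median kernel.
    """
    channel = np.asarray(channel)
    if channel.ndim != 2 or min(channel.shape) < 3:
        raise ValueError("channel must be a 2-D image of at least 3x3 pixels")
    k = 2 * int(radius) + 1
    if min(channel.shape) < k:
        raise ValueError(
            f"image {channel.shape} smaller than median kernel; "
            f"needs at least {k}x{k} pixels")
    u8 = np.clip(np.rint(channel), 0, 255).astype(np.uint8)
    bg = rank.median(u8, footprint_rectangle((k, k)))
    return bg.astype(np.float64)


def foreground_deviation(channel, background, polarity: str = "bright"):
    """Deviation from background in the colony-contrast direction, >= 0."""
    diff = np.asarray(channel, dtype=np.float64) - background
    if polarity == "bright":
        return np.clip(diff, 0.0, None)
    if polarity == "dark":
        return np.clip(-diff, 0.0, None)
    raise ValueError("polarity must be 'bright' or 'dark'")


def detect_polarity(channels, backgrounds, mask=None) -> str:
    """Pick the dominant deviation direction across all channels.

    Bright-on-dark material (e.g. most bacterial colonies on agar) yields
    mostly positive deviations; dark colonies the opposite.  Ties go to
    bright.
    """
    pos = neg = 0.0
    for ch, bg in zip(channels, backgrounds):
        diff = np.asarray(ch, dtype=np.float64) - bg
        if mask is not None:
            diff = diff[mask]
        pos += float(np.clip(diff, 0.0, None).sum())
        neg += float(np.clip(-diff, 0.0, None).sum())
    return "bright" if pos >= neg else "dark"


def enhance_channel(foreground: np.ndarray, sigma: float = 1.0,
                    gain: float = 2.0) -> np.ndarray:
    """Subtract the positive Laplacian-of-Gaussian response from the image.

    The scale-normalised LoG (``-sigma**2 * gaussian_laplace``) is strongly
    positive on structures of width comparable to ``sigma`` — cracks, rim
    highlights, specks — and near zero on the interior of wide plateaus,
    so subtracting its positive part (times ``gain``) suppresses thin
    clutter while leaving colony interiors untouched.  Output is clipped
    at zero and never exceeds the input.
    """
    fg = np.asarray(foreground, dtype=np.float64)
    logp = -(sigma ** 2) * ndimage.gaussian_laplace(fg, sigma)
    return np.clip(fg - gain * np.clip(logp, 0.0, None), 0.0, None)


def merge_channels(enhanced, mask=None) -> np.ndarray:
    """Min-max normalise each channel to [0, 255] and average them.

    Accepts one or three channels; a constant channel (max == min) cannot
    be normalised and contributes zeros, with a logged warning.  When a
    mask is supplied, the normalisation range is taken over masked pixels
    only (but applied everywhere).
    """
    enhanced = [np.asarray(ch, dtype=np.float64) for ch in enhanced]
    if len(enhanced) not in (1, 3):
        raise ValueError("expected 1 or 3 channels")
    shape = enhanced[0].shape
    if any(ch.shape != shape for ch in enhanced):
        raise ValueError("channels must share one shape")
    out = np.zeros(shape, dtype=np.float64)
    for i, ch in enumerate(enhanced):
        sel = ch[mask] if mask is not None else ch
        lo, hi = float(sel.min()), float(sel.max())
        if hi == lo:
            log.warning("channel %d is constant; it contributes zeros", i)
            continue
        out += np.clip((ch - lo) * (255.0 / (hi - lo)), 0.0, 255.0)
    grey = out / len(enhanced)
    return np.clip(np.rint(grey), 0, 255).astype(np.uint8)


def preprocess_image(image, *, r_max: float, params=None, mask=None):
    """Full preprocessing of an RGB (or grey) image.

    Parameters
    ----------
    image : (H, W, 3) or (H, W) array
    r_max : float
        Largest expected colony radius; sets the default median kernel.
    params : PreprocessParams, optional
    mask : bool array, optional
        Restrict normalisation and polarity detection to these pixels;
        pixels outside are zeroed in the output.

    Returns
    -------
    grey : (H, W) uint8 working image
    foregrounds : list of per-channel background-subtracted channels
        (polarity-corrected, un-normalised) — used later for "corrected"
        colour measurements.
    """
    from .config import PreprocessParams
    params = params or PreprocessParams()

    image = np.asarray(image)
    channels = ([image[:, :, i] for i in range(3)] if image.ndim == 3
                else [image])
    radius = params.median_radius
    if radius is None:
        radius = int(math.ceil(r_max))
    radius = min(radius, (min(channels[0].shape) - 1) // 2)

    backgrounds = [estimate_background(ch, radius) for ch in channels]
    polarity = params.polarity
    if polarity == "auto":
        polarity = detect_polarity(channels, backgrounds, mask)
    foregrounds = [foreground_deviation(ch, bg, polarity)
                   for ch, bg in zip(channels, backgrounds)]
    if params.noise_floor > 0:
        # noise floor: deviations indistinguishable from pixel noise are
        # zeroed, so normalisation cannot stretch noise to full range on
        # a near-empty plate
        for fg, ch, bg in zip(foregrounds, channels, backgrounds):
            dev = np.asarray(ch, dtype=np.float64) - bg
            sel = dev[mask] if mask is not None else dev
            sigma = 1.4826 * float(np.median(np.abs(sel - np.median(sel))))
            fg[fg < params.noise_floor * sigma] = 0.0
    enhanced = [enhance_channel(fg, params.log_sigma, params.log_gain)
                for fg in foregrounds]
    if mask is not None:
        enhanced = [np.where(mask, ch, 0.0) for ch in enhanced]
        foregrounds = [np.where(mask, fg, 0.0) for fg in foregrounds]
    grey = merge_channels(enhanced, mask)
    if mask is not None:
        grey = np.where(mask, grey, 0).astype(np.uint8)
    return grey, foregrounds
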