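"""Itti-style intensity and color activation maps.

Implements the classic bottom-up channel machinery: a Gaussian pyramid,
center–surround (difference-of-Gaussians) maps between pyramid levels, the
peak-promoting normalization operator, and the intensity and opponent-color
activation maps built from them.

Scales.  The original formulation takes centers c ∈ {2,3,4} and surround
offsets δ ∈ {3,4} on 640×480 inputs; at the 170×128 working resolution used
here those surround levels degenerate below the minimum pyramid size, so the
defaults are c ∈ {2,3}, d ∈ {2,3}, and any (c, d) pair whose surround level
does not exist in the pyramid is skipped.  Each center–surround map is
normalized, upsampled to the working resolution, and summed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .contour import ActivationMap, normalize_minmax
from .image_pipeline import Image

__all__ = ["GaussianPyramid", "build_pyramid", "center_surround",
           "itti_normalize", "intensity_activation", "color_activation",
           "broad_color_channels"]

MIN_LEVEL_DIM = 4
MIN_INPUT_DIM = 64
DEFAULT_CENTERS = (2, 3)
DEFAULT_SURROUND_OFFSETS = (2, 3)
LOCAL_MAX_SIZE = 7
LOCAL_MAX_THRESHOLD = 0.05


@dataclass(frozen=True)
class GaussianPyramid:
    """Dyadic Gaussian pyramid; level 0 is the working resolution."""

    levels: tuple[np.ndarray, ...]

    def __len__(self) -> int:
        return len(self.levels)

    def __getitem__(self, k: int) -> np.ndarray:
        return self.levels[k]


def build_pyramid(plane: np.ndarray, blur_sigma: float = 1.0) -> GaussianPyramid:
    """Blur (σ = ``blur_sigma``) then 2× decimate, down to min dimension ≥ 4."""
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError("pyramid input must be a 2-D plane")
    if min(plane.shape) < MIN_INPUT_DIM:
        raise ValueError(
            f"pyramid input too small: {plane.shape} (min dimension {MIN_INPUT_DIM})")
    levels = [plane]
    while True:
        blurred = ndimage.gaussian_filter(levels[-1], blur_sigma, mode="mirror")
        nxt = blurred[::2, ::2]
        if min(nxt.shape) < MIN_LEVEL_DIM:
            break
        levels.append(nxt)
    return GaussianPyramid(tuple(levels))


def _upsample(plane: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    if plane.shape == tuple(shape):
        return plane
    return _sk_resize(plane, shape, order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def center_surround(pyr: GaussianPyramid, c: int, d: int) -> np.ndarray:
    """|level_c − upsample(level_{c+d})|, computed at level c's resolution."""
    if not (0 <= c < len(pyr)):
        raise ValueError(f"center level {c} not in pyramid of depth {len(pyr)}")
    if d < 1 or c + d >= len(pyr):
        raise ValueError(
            f"surround level {c}+{d} not in pyramid of depth {len(pyr)}")
    center = pyr[c]
    surround = _upsample(pyr[c + d], center.shape)
    return np.abs(center - surround)


def itti_normalize(plane: np.ndarray) -> np.ndarray:
    """Peak-promoting normalization.

    Rescales the plane to [0, 1], finds local maxima over a 7×7 neighborhood
    (value ≥ 0.05), and multiplies by (1 − m̄)² where m̄ is the mean of the
    local maxima other than the global one.  A map with one dominant peak is
    kept; a map of many similar peaks is suppressed.  A zero plane stays zero.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if not np.all(np.isfinite(plane)):
        raise ValueError("cannot normalize a plane with NaN/Inf")
    scaled = normalize_minmax(plane)
    if scaled.max() == 0.0:
        return scaled
    is_peak = (scaled == ndimage.maximum_filter(
        scaled, size=LOCAL_MAX_SIZE, mode="constant", cval=-np.inf))
    is_peak &= scaled >= LOCAL_MAX_THRESHOLD
    peak_vals = np.sort(scaled[is_peak])
    # drop one occurrence of the global maximum; the rest are the "other"
    # local maxima (identical repeated peaks therefore yield m̄ ≈ 1)
    others = peak_vals[:-1]
    m_bar = float(others.mean()) if others.size else 0.0
    return scaled * (1.0 - m_bar) ** 2


def _valid_pairs(n_levels: int, centers: tuple[int, ...],
                 offsets: tuple[int, ...]) -> list[tuple[int, int]]:
    return [(c, d) for c in centers for d in offsets if c + d < n_levels]


def _channel_sum(pyramids: list[GaussianPyramid], shape: tuple[int, int],
                 centers: tuple[int, ...], offsets: tuple[int, ...]) -> np.ndarray:
    total = np.zeros(shape, dtype=np.float64)
    for pyr in pyramids:
        pairs = _valid_pairs(len(pyr), centers, offsets)
        if not pairs:
            raise ValueError("pyramid too shallow for any center–surround pair")
        for c, d in pairs:
            cs = itti_normalize(center_surround(pyr, c, d))
            total += _upsample(cs, shape)
    return total


def intensity_activation(img: Image,
                         centers: tuple[int, ...] = DEFAULT_CENTERS,
                         offsets: tuple[int, ...] = DEFAULT_SURROUND_OFFSETS,
                         blur_sigma: float = 1.0) -> ActivationMap:
    """Intensity channel: center–surround on the mean-of-channels plane."""
    intensity = img.as_gray()
    pyr = build_pyramid(intensity, blur_sigma)
    total = _channel_sum([pyr], intensity.shape, centers, offsets)
    return ActivationMap(values=total, source="intensity")


def broad_color_channels(img: Image) -> tuple[np.ndarray, np.ndarray,
                                              np.ndarray, np.ndarray]:
    """Broadly-tuned R, G, B, Y planes, each clipped at zero.

    R = r − (g+b)/2, G = g − (r+b)/2, B = b − (r+g)/2,
    Y = (r+g)/2 − |r−g|/2 − b.
    """
    if img.channels != 3:
        raise ValueError("broad color channels need a 3-channel image")
    r = img.pixels[:, :, 0]
    g = img.pixels[:, :, 1]
    b = img.pixels[:, :, 2]
    R = np.maximum(r - (g + b) / 2.0, 0.0)
    G = np.maximum(g - (r + b) / 2.0, 0.0)
    B = np.maximum(b - (r + g) / 2.0, 0.0)
    Y = np.maximum((r + g) / 2.0 - np.abs(r - g) / 2.0 - b, 0.0)
    return R, G, B, Y


def color_activation(img: Image,
                     centers: tuple[int, ...] = DEFAULT_CENTERS,
                     offsets: tuple[int, ...] = DEFAULT_SURROUND_OFFSETS,
                     blur_sigma: float = 1.0) -> ActivationMap:
    """Color channel: center–surround on the R−G and B−Y opponent planes.

    A grayscale input (or r = g = b everywhere) has vanishing opponency and
    yields an identically-zero map.
    """
    shape = (img.height, img.width)
    if img.channels != 3:
        return ActivationMap(values=np.zeros(shape), source="color")
    R, G, B, Y = broad_color_channels(img)
    rg_pyr = build_pyramid(R - G, blur_sigma)
    by_pyr = build_pyramid(B - Y, blur_sigma)
    total = _channel_sum([rg_pyr, by_pyr], shape, centers, offsets)
    return ActivationMap(values=total, source="color")
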