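"""Linear structure tensor and its eigenvalue sum/difference maps.

For an image with channels I_i the tensor field is

    J_σ = [[G, F], [F, H]],
    G = K_σ ∗ Σ_i (∂I_i/∂x)²,  F = K_σ ∗ Σ_i (∂I_i/∂x)(∂I_i/∂y),
    H = K_σ ∗ Σ_i (∂I_i/∂y)²,

with K_σ a normalized Gaussian of standard deviation σ (truncated at 4σ,
mirror border handling).  J_σ is positive semidefinite at every pixel, so
its eigenvalues satisfy λ1 ≥ λ2 ≥ 0.  The maps of interest never need an
eigendecomposition:

    λ1 − λ2 = sqrt((G − H)² + 4F²)   (anisotropy / edge strength)
    λ1 + λ2 = G + H                  (total gradient energy)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_pipeline import Image

__all__ = ["TensorField", "EigenMaps", "image_gradients", "compute_tensor",
           "eigen_sum_diff", "GAUSS_TRUNCATE"]

# kernel support in standard deviations; the effective radius is
# round(GAUSS_TRUNCATE * sigma)
GAUSS_TRUNCATE = 4.0

_PSD_EPS = 1e-9


@dataclass(frozen=True)
class TensorField:
    """Per-pixel symmetric 2×2 tensor stored as three scalar planes."""

    g: np.ndarray   # smoothed Σ (∂I/∂x)²
    f: np.ndarray   # smoothed Σ (∂I/∂x)(∂I/∂y)
    h: np.ndarray   # smoothed Σ (∂I/∂y)²
    sigma: float

    def __post_init__(self) -> None:
        if not (self.g.shape == self.f.shape == self.h.shape):
            raise ValueError("tensor planes must share a shape")
        if np.any(self.g < -_PSD_EPS) or np.any(self.h < -_PSD_EPS):
            raise ValueError("diagonal tensor planes must be non-negative")
        if np.any(self.f ** 2 > self.g * self.h + _PSD_EPS):
            raise ValueError("tensor field is not positive semidefinite")


@dataclass(frozen=True)
class EigenMaps:
    diff: np.ndarray   # λ1 − λ2
    sum: np.ndarray    # λ1 + λ2


def image_gradients(img: Image) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel ∂I/∂x and ∂I/∂y, each shaped (H, W, C).

    Central differences in the interior, one-sided at the borders, unit
    pixel spacing.
    """
    px = img.pixels
    if px.shape[0] < 2 or px.shape[1] < 2:
        raise ValueError("gradients need at least 2 rows and 2 columns")
    dy, dx = np.gradient(px, axis=(0, 1))
    return dx, dy


def compute_tensor(img: Image, sigma: float = 2.0) -> TensorField:
    """Build the linear structure tensor field at Gaussian scale ``sigma``."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    dx, dy = image_gradients(img)
    gxx = (dx * dx).sum(axis=2)
    gxy = (dx * dy).sum(axis=2)
    gyy = (dy * dy).sum(axis=2)
    smooth = lambda p: ndimage.gaussian_filter(p, sigma, mode="mirror",
                                               truncate=GAUSS_TRUNCATE)
    g, f, h = smooth(gxx), smooth(gxy), smooth(gyy)
    # smoothing a PSD field with a non-negative kernel stays PSD; clip the
    # float dust so the invariant holds exactly
    g = np.maximum(g, 0.0)
    h = np.maximum(h, 0.0)
    return TensorField(g=g, f=f, h=h, sigma=float(sigma))


def eigen_sum_diff(tf: TensorField) -> EigenMaps:
    """Closed-form λ1−λ2 and λ1+λ2 planes; no explicit eigendecomposition."""
    diff = np.sqrt((tf.g - tf.h) ** 2 + 4.0 * tf.f ** 2)
    total = tf.g + tf.h
    return EigenMaps(diff=diff, sum=total)
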