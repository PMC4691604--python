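"""Edge and corner feature maps and the contour activation map.

From the eigenvalue planes of the structure tensor:

    A = λ1 − λ2          edge strength (anisotropy: one dominant direction)
    B = λ2               corner strength (both eigenvalues large)
    C_T = (N(A) + N(B)) / 2

where N(·) is a min–max rescale to [0, 1].  An alternative corner measure
B = λ1 + λ2 (total gradient energy, the tensor trace) is available via
``corner_variant="trace"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_tensor import EigenMaps

__all__ = ["FeatureMap", "ActivationMap", "edge_map", "corner_map",
           "normalize_minmax", "contour_activation"]


@dataclass(frozen=True)
class FeatureMap:
    """Single-channel non-negative feature plane."""

    values: np.ndarray
    kind: str  # "edge" | "corner"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(v)):
            raise ValueError("feature map contains non-finite values")
        if v.min() < 0:
            raise ValueError("feature map must be non-negative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ActivationMap:
    """Normalized per-channel activation plane."""

    values: np.ndarray
    source: str  # "contour" | "intensity" | "color"

    @property
    def peak(self) -> float:
        return float(self.values.max()) if self.values.size else 0.0


def edge_map(em: EigenMaps) -> FeatureMap:
    """Edge feature map A = λ1 − λ2."""
    return FeatureMap(values=em.diff, kind="edge")


def corner_map(em: EigenMaps, variant: str = "lambda2") -> FeatureMap:
    """Corner feature map B.

    ``variant="lambda2"`` (default) uses B = λ2 = (sum − diff)/2, which is
    large only where both eigenvalues are large; ``variant="trace"`` uses
    B = λ1 + λ2.
    """
    if variant == "lambda2":
        values = np.maximum((em.sum - em.diff) / 2.0, 0.0)
    elif variant == "trace":
        values = np.maximum(em.sum, 0.0)
    else:
        raise ValueError(f"unknown corner variant {variant!r}")
    return FeatureMap(values=values, kind="corner")


def normalize_minmax(fm: FeatureMap | np.ndarray) -> np.ndarray:
    """Affine rescale to [0, 1]; a constant plane maps to all zeros."""
    v = fm.values if isinstance(fm, FeatureMap) else np.asarray(fm, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("cannot normalize a plane with NaN/Inf")
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        return np.zeros_like(v, dtype=np.float64)
    return (v - lo) / (hi - lo)


def contour_activation(a: FeatureMap, b: FeatureMap) -> ActivationMap:
    """Contour activation map C_T = (N(A) + N(B)) / 2."""
    if a.values.shape != b.values.shape:
        raise ValueError(
            f"shape mismatch: A is {a.values.shape}, B is {b.values.shape}")
    values = (normalize_minmax(a) + normalize_minmax(b)) / 2.0
    return ActivationMap(values=values, source="contour")
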