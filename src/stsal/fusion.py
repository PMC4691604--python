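"""Channel fusion and the end-to-end structure-tensor saliency model.

The saliency map averages the three activation maps with equal weights
after applying the peak-promoting normalization ⊕ to each:

    S = (⊕C_L + ⊕I + ⊕C_T) / 3

(C_L color, I intensity, C_T contour).  Note the contour map is built with
a plain min–max N(·) and then still passes through ⊕ here — the two
normalizations are distinct operators and both are applied.  The output is
min–max rescaled to [0, 1] as a presentation convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import STConfig
from .contour import (ActivationMap, contour_activation, corner_map, edge_map,
                      normalize_minmax)
from .image_pipeline import Image, resize_image
from .itti_channels import color_activation, intensity_activation, itti_normalize
from .structure_tensor import compute_tensor, eigen_sum_diff

__all__ = ["SaliencyMap", "fuse", "contour_channel", "st_saliency"]


@dataclass(frozen=True)
class SaliencyMap:
    """Final saliency plane in [0, 1] plus the config that produced it."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("saliency map must be a 2-D plane")
        if not np.all(np.isfinite(v)):
            raise ValueError("saliency map contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def fuse(cl: ActivationMap, ii: ActivationMap, ct: ActivationMap,
         provenance: dict | None = None) -> SaliencyMap:
    """Equal-weight fusion of the color, intensity and contour channels."""
    shapes = {cl.values.shape, ii.values.shape, ct.values.shape}
    if len(shapes) != 1:
        raise ValueError(f"activation maps disagree in shape: {sorted(shapes)}")
    s = (itti_normalize(cl.values) + itti_normalize(ii.values)
         + itti_normalize(ct.values)) / 3.0
    return SaliencyMap(values=normalize_minmax(s), provenance=provenance or {})


def contour_channel(img: Image, cfg: STConfig) -> ActivationMap:
    """Structure tensor → eigen maps → edge/corner → contour activation."""
    if cfg.colorspace == "lab":
        from skimage.color import rgb2lab
        px = img.pixels if img.channels == 3 else np.repeat(img.pixels, 3, axis=2)
        lab = rgb2lab(px)
        # bring the channels to comparable ranges before differentiating
        lab = lab / np.array([100.0, 128.0, 128.0])
        tensor_input = Image(np.clip((lab + 1.0) / 2.0, 0.0, 1.0))
    else:
        tensor_input = img
    tf = compute_tensor(tensor_input, sigma=cfg.sigma)
    em = eigen_sum_diff(tf)
    a = edge_map(em)
    b = corner_map(em, variant=cfg.corner_variant)
    if cfg.contour_norm == "itti":
        values = (itti_normalize(a.values) + itti_normalize(b.values)) / 2.0
        return ActivationMap(values=values, source="contour")
    return contour_activation(a, b)


def st_saliency(img: Image, cfg: STConfig | None = None) -> SaliencyMap:
    """Run the full model on one image.

    Resizes to the working resolution, computes the color and intensity
    activation maps and the structure-tensor contour map, and fuses them.
    Deterministic: the same image and config always give a bit-identical map.
    """
    cfg = cfg or STConfig()
    work = resize_image(img, cfg.working_size)
    cl = color_activation(work, cfg.centers, cfg.surround_offsets,
                          cfg.pyramid_blur_sigma)
    ii = intensity_activation(work, cfg.centers, cfg.surround_offsets,
                              cfg.pyramid_blur_sigma)
    ct = contour_channel(work, cfg)
    return fuse(cl, ii, ct, provenance=cfg.snapshot())
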