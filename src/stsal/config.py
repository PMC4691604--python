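"""Model configuration: every tunable of the saliency pipeline in one place."""

from __future__ import annotations

import os
from dataclasses import dataclass, asdict, replace


@dataclass(frozen=True)
class STConfig:
    """Configuration for the structure-tensor saliency model.

    sigma            Gaussian scale (std dev, pixels) of tensor smoothing at
                     the working resolution.
    working_size     (width, height) every input is resized to before any
                     processing; the published evaluation size.
    corner_variant   "lambda2" (B = λ2) or "trace" (B = λ1 + λ2).
    colorspace       channels fed to the structure tensor: "rgb" or "lab".
    contour_norm     N(·) inside the contour map: "minmax" or "itti"
                     (ablation option).
    centers/surround_offsets
                     pyramid levels for center–surround maps.
    """

    sigma: float = 2.0
    working_size: tuple[int, int] = (170, 128)
    corner_variant: str = "lambda2"
    colorspace: str = "rgb"
    contour_norm: str = "minmax"
    centers: tuple[int, ...] = (2, 3)
    surround_offsets: tuple[int, ...] = (2, 3)
    pyramid_blur_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.corner_variant not in ("lambda2", "trace"):
            raise ValueError(f"unknown corner_variant {self.corner_variant!r}")
        if self.colorspace not in ("rgb", "lab"):
            raise ValueError(f"unknown colorspace {self.colorspace!r}")
        if self.contour_norm not in ("minmax", "itti"):
            raise ValueError(f"unknown contour_norm {self.contour_norm!r}")

    def snapshot(self) -> dict:
        """JSON-able provenance record."""
        return asdict(self)

    def with_(self, **kwargs) -> "STConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "STConfig":
        """Read a key=value config file mirroring the CLI flags.

        Recognized keys: sigma, size (WxH), corner_variant, colorspace,
        contour_norm, centers / surround_offsets (comma-separated ints),
        pyramid_blur_sigma.  '#' starts a comment.
        """
        kwargs: dict = {}
        with open(os.fspath(path)) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, val = (s.strip() for s in line.split("=", 1))
                if key == "sigma":
                    kwargs["sigma"] = float(val)
                elif key == "size":
                    w, h = val.lower().split("x")
                    kwargs["working_size"] = (int(w), int(h))
                elif key in ("corner_variant", "colorspace", "contour_norm"):
                    kwargs[key] = val
                elif key in ("centers", "surround_offsets"):
                    kwargs[key] = tuple(int(s) for s in val.split(","))
                elif key == "pyramid_blur_sigma":
                    kwargs["pyramid_blur_sigma"] = float(val)
                else:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        return cls(**kwargs)
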