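"""Image I/O, resizing, fixation files, and synthetic pop-out fixtures.

All images are carried as ``Image`` objects: H×W×C float arrays in [0, 1]
with C ∈ {1, 3} (RGB order for 3-channel data).  The coordinate convention
throughout the package is x = column, y = row, 0-based, with pixel centers
at integer coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "Image",
    "FixationSet",
    "Rect",
    "load_image",
    "save_image",
    "resize_image",
    "save_saliency",
    "load_matrix_text",
    "save_matrix_text",
    "read_fixations",
    "write_fixations",
    "make_popout_image",
    "make_fixations",
]

MIN_DIM = 8


@dataclass(frozen=True)
class Image:
    """A float raster in [0, 1], shape (H, W, C) with C in {1, 3}."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3 or px.shape[2] not in (1, 3):
            raise ValueError(f"expected H×W×C with C in {{1,3}}, got shape {px.shape}")
        if px.shape[0] < MIN_DIM or px.shape[1] < MIN_DIM:
            raise ValueError(f"image too small: {px.shape[1]}×{px.shape[0]} (min {MIN_DIM}×{MIN_DIM})")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("image values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]

    def as_gray(self) -> np.ndarray:
        """Mean over channels, shape (H, W)."""
        return self.pixels.mean(axis=2)


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle [x0, x1) × [y0, y1); empty when x0 >= x1."""

    x0: int
    y0: int
    x1: int
    y1: int

    @property
    def empty(self) -> bool:
        return self.x1 <= self.x0 or self.y1 <= self.y0

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def mask(self, height: int, width: int) -> np.ndarray:
        m = np.zeros((height, width), dtype=bool)
        if not self.empty:
            m[max(self.y0, 0): min(self.y1, height), max(self.x0, 0): min(self.x1, width)] = True
        return m

    def dilate(self, r: int) -> "Rect":
        return Rect(self.x0 - r, self.y0 - r, self.x1 + r, self.y1 + r)


@dataclass(frozen=True)
class FixationSet:
    """Eye-fixation coordinates for one image, in that image's pixel units."""

    points: tuple[tuple[float, float], ...]
    image_id: str = ""

    def __post_init__(self) -> None:
        pts = tuple((float(x), float(y)) for x, y in self.points)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=np.float64).reshape(-1, 2)


def load_image(path: str | os.PathLike) -> Image:
    """Read a PNG/JPEG/PPM file into a float Image in [0, 1].

    8-bit (and 16-bit) integer data are divided by their type maximum;
    RGBA alpha is dropped; grayscale stays single-channel.
    """
    path = os.fspath(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder failures carry the path
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path!r}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return Image(np.clip(arr, 0.0, 1.0))


def save_image(img: Image, path: str | os.PathLike) -> None:
    """Write an Image as 8-bit PNG (or whatever the extension selects)."""
    data = np.rint(img.pixels * 255.0).astype(np.uint8)
    if data.shape[2] == 1:
        data = data[:, :, 0]
    iio.imwrite(os.fspath(path), data)


def resize_image(img: Image, target: tuple[int, int] = (170, 128)) -> Image:
    """Bilinear resize to ``target = (width, height)``.

    The default target is the 170×128 working resolution at which the whole
    model operates.  A constant image resizes to the same constant.
    """
    width, height = int(target[0]), int(target[1])
    if width < MIN_DIM or height < MIN_DIM:
        raise ValueError(f"target dimensions must be ≥ {MIN_DIM}, got {width}×{height}")
    if (img.width, img.height) == (width, height):
        return img
    out = _sk_resize(
        img.pixels, (height, width), order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return Image(np.clip(out, 0.0, 1.0))


# ---------------------------------------------------------------------------
# saliency-map and matrix text output

def save_matrix_text(plane: np.ndarray, path: str | os.PathLike) -> None:
    """Lossless float sidecar: one row per line, space-separated."""
    np.savetxt(os.fspath(path), np.asarray(plane, dtype=np.float64), fmt="%.17g")


def load_matrix_text(path: str | os.PathLike) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(os.fspath(path), dtype=np.float64))


def save_saliency(values: np.ndarray, png_path: str | os.PathLike,
                  txt_path: str | os.PathLike | None = None) -> None:
    """Write a saliency plane as min–max-scaled 8-bit PNG plus float sidecar."""
    v = np.asarray(values, dtype=np.float64)
    lo, hi = float(v.min()), float(v.max())
    scaled = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
    iio.imwrite(os.fspath(png_path), np.rint(scaled * 255.0).astype(np.uint8))
    if txt_path is not None:
        save_matrix_text(v, txt_path)


# ---------------------------------------------------------------------------
# fixation files: plain text, one "x y" pair per line, '#' comments

def read_fixations(path: str | os.PathLike, image_id: str | None = None,
                   one_based: bool = False) -> FixationSet:
    """Parse a fixation file.  ``one_based=True`` shifts coordinates by −1."""
    path = os.fspath(path)
    pts: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'x y', got {raw!r}")
            x, y = float(parts[0]), float(parts[1])
            if one_based:
                x, y = x - 1.0, y - 1.0
            pts.append((x, y))
    if image_id is None:
        image_id = os.path.splitext(os.path.basename(path))[0]
    return FixationSet(tuple(pts), image_id=image_id)


def write_fixations(fix: FixationSet, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        for x, y in fix.points:
            fh.write(f"{x:.3f} {y:.3f}\n")


# ---------------------------------------------------------------------------
# synthetic fixtures

_KINDS = ("blank", "edge", "crossing", "color_popout")


def make_popout_image(kind: str, size: tuple[int, int] = (170, 128),
                      seed: int = 0) -> tuple[Image, Rect]:
    """Generate a deterministic pop-out stimulus and its ground-truth region.

    kind:
      blank        — constant mid-gray; empty target region.
      edge         — vertical luminance step; target is the edge column band.
      crossing     — one full-width and one full-height bright line crossing
                     on a dark field; target is a box around the crossing
                     (the only corner-rich locus).
      color_popout — dense grid of green bars with a single red bar of equal
                     luminance on mid-gray; target encloses the red bar.

    The seed jitters positions but never the geometry class, so the returned
    target region is exact by construction.  Non-blank stimuli carry a small
    seeded luminance noise (σ = 0.01, identical across channels) emulating
    sensor noise; without it, perfectly uniform ridges are degenerate inputs
    to the peak-promoting normalization.
    """
    width, height = int(size[0]), int(size[1])
    if width < 32 or height < 32:
        raise ValueError(f"fixture size must be ≥ 32×32, got {width}×{height}")
    rng = np.random.default_rng(seed)

    def _noisy(px: np.ndarray) -> np.ndarray:
        noise = rng.normal(0.0, 0.01, (height, width, 1))
        return np.clip(px + noise, 0.0, 1.0)

    if kind == "blank":
        px = np.full((height, width, 3), 0.5)
        return Image(px), Rect(0, 0, 0, 0)

    if kind == "edge":
        px = np.full((height, width, 3), 0.25)
        col = int(rng.integers(width // 3, 2 * width // 3))
        px[:, col:, :] = 0.75
        band = 5  # σ=2 tensor smoothing spreads the response a few pixels
        return Image(_noisy(px)), Rect(col - band, 0, col + band, height)

    if kind == "crossing":
        px = np.full((height, width, 3), 0.1)
        cx = int(rng.integers(width // 3, 2 * width // 3))
        cy = int(rng.integers(height // 3, 2 * height // 3))
        px[cy - 1: cy + 2, :, :] = 0.9   # full-width horizontal line
        px[:, cx - 1: cx + 2, :] = 0.9   # full-height vertical line
        r = 8
        return Image(_noisy(px)), Rect(cx - r, cy - r, cx + r + 1, cy + r + 1)

    if kind == "color_popout":
        px = np.full((height, width, 3), 0.5)
        bar_w, bar_h, step = 5, 12, 16
        # tile the whole field, clipping boundary bars, so the only odd item
        # is the red bar (a truncated array would make its own rim salient)
        cols = list(range(-bar_w // 2, width, step))
        rows = list(range(-bar_h // 2, height, step))
        cells = [(c, r) for c in cols for r in rows]
        interior = [(c, r) for c, r in cells
                    if step <= c < width - step - bar_w
                    and step <= r < height - step - bar_h]
        tx, ty = interior[int(rng.integers(len(interior)))]
        for c, r in cells:
            color = (1.0, 0.0, 0.0) if (c, r) == (tx, ty) else (0.0, 1.0, 0.0)
            px[max(r, 0): r + bar_h, max(c, 0): c + bar_w, :] = color
        # bar bounding box + margin for the smoothing-induced peak shift
        target = Rect(tx, ty, tx + bar_w, ty + bar_h).dilate(2)
        return Image(_noisy(px)), target

    raise ValueError(f"unknown fixture kind {kind!r}; expected one of {_KINDS}")


def make_fixations(n: int, size: tuple[int, int], seed: int,
                   region: Rect | None = None, center_sigma: float | None = None,
                   image_id: str = "") -> FixationSet:
    """Simulate a fixation set on an image of ``size = (width, height)``.

    With ``region`` set, points are drawn uniformly inside it (clipped to the
    image); with ``center_sigma`` set, points are Gaussian around the image
    center with that standard deviation in pixels (a center-bias model);
    otherwise uniform over the image.
    """
    if n < 1:
        raise ValueError("need at least one fixation")
    width, height = int(size[0]), int(size[1])
    rng = np.random.default_rng(seed)
    if region is not None and not region.empty:
        x0, x1 = max(region.x0, 0), min(region.x1, width)
        y0, y1 = max(region.y0, 0), min(region.y1, height)
        xs = rng.uniform(x0, x1 - 1e-9, n)
        ys = rng.uniform(y0, y1 - 1e-9, n)
    elif center_sigma is not None:
        xs = np.clip(rng.normal((width - 1) / 2, center_sigma, n), 0, width - 1)
        ys = np.clip(rng.normal((height - 1) / 2, center_sigma, n), 0, height - 1)
    else:
        xs = rng.uniform(0, width - 1e-9, n)
        ys = rng.uniform(0, height - 1e-9, n)
    return FixationSet(tuple(zip(xs.tolist(), ys.tolist())), image_id=image_id)
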