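"""Image ingestion and normalization.

Radiographs (DICOM or PNG) are loaded as grayscale arrays, resized onto a
fixed 1333×800 detector canvas with the aspect ratio preserved and the
shorter side zero-padded (split centered), then contrast-enhanced with
CLAHE.  The :class:`CanvasTransform` records the scale and padding so that
landmark coordinates can be mapped losslessly between original and canvas
space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from .geometry import Point2D

__all__ = [
    "CanvasTransform",
    "DEFAULT_CANVAS",
    "load_radiograph",
    "resize_pad",
    "clahe_enhance",
    "map_landmarks",
]

DEFAULT_CANVAS: Tuple[int, int] = (1333, 800)  # (width, height)


class PaddedRegionError(ValueError):
    """A canvas point lies in the zero-padded margin and has no original
    preimage."""


@dataclass(frozen=True)
class CanvasTransform:
    """Affine original→canvas mapping: scale then centered zero padding."""

    scale: float
    pad_x: float
    pad_y: float
    original_size: Tuple[int, int]  # (w, h)
    canvas_size: Tuple[int, int] = DEFAULT_CANVAS

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def to_canvas(self, p: Point2D) -> Point2D:
        return Point2D(p.x * self.scale + self.pad_x, p.y * self.scale + self.pad_y)

    def to_original(self, p: Point2D) -> Point2D:
        x = (p.x - self.pad_x) / self.scale
        y = (p.y - self.pad_y) / self.scale
        w, h = self.original_size
        if x < -1e-9 or y < -1e-9 or x > w + 1e-9 or y > h + 1e-9:
            raise PaddedRegionError(
                f"canvas point ({p.x}, {p.y}) lies in the padded margin"
            )
        return Point2D(x, y)

    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "pad_x": self.pad_x,
            "pad_y": self.pad_y,
            "original_size": list(self.original_size),
            "canvas_size": list(self.canvas_size),
        }

    @staticmethod
    def from_dict(d: dict) -> "CanvasTransform":
        return CanvasTransform(
            scale=float(d["scale"]),
            pad_x=float(d["pad_x"]),
            pad_y=float(d["pad_y"]),
            original_size=tuple(d["original_size"]),
            canvas_size=tuple(d.get("canvas_size", DEFAULT_CANVAS)),
        )


def load_radiograph(path, fmt: Optional[str] = None):
    """Load a radiograph as a 2-D grayscale array.

    Returns ``(image, pixel_spacing_mm)``; the spacing comes from DICOM
    metadata (PixelSpacing, falling back to ImagerPixelSpacing) and is
    ``None`` for PNG or when absent.  Multi-frame DICOM is rejected.
    """
    path = str(path)
    if fmt is None:
        fmt = "dicom" if path.lower().endswith((".dcm", ".dicom")) else "png"
    if fmt == "dicom":
        import pydicom

        ds = pydicom.dcmread(path)
        nframes = int(getattr(ds, "NumberOfFrames", 1) or 1)
        if nframes > 1:
            raise ValueError(f"multi-frame DICOM not supported ({nframes} frames)")
        arr = ds.pixel_array
        if arr.ndim != 2:
            raise ValueError(f"expected 2-D pixel data, got shape {arr.shape}")
        spacing = getattr(ds, "PixelSpacing", None) or getattr(
            ds, "ImagerPixelSpacing", None
        )
        spacing_mm = float(spacing[0]) if spacing is not None else None
        return np.asarray(arr), spacing_mm
    elif fmt == "png":
        with Image.open(path) as im:
            if im.mode not in ("L", "I", "I;16", "F"):
                im = im.convert("L")
            arr = np.asarray(im)
        return arr, None
    raise ValueError(f"unknown format {fmt!r}")


def resize_pad(image: np.ndarray, canvas: Tuple[int, int] = DEFAULT_CANVAS):
    """Scale ``image`` to fit the canvas (aspect preserved, bilinear) and
    zero-pad the shorter dimension, split centered (floor top/left, ceil
    bottom/right on odd remainders).

    Returns ``(canvas_image, CanvasTransform)``.
    """
    from skimage.transform import resize as _sk_resize

    if image.ndim != 2:
        raise ValueError(f"expected 2-D grayscale image, got shape {image.shape}")
    h, w = image.shape
    if h == 0 or w == 0:
        raise ValueError("empty image")
    cw, ch = canvas
    scale = min(cw / w, ch / h)
    nw, nh = int(round(w * scale)), int(round(h * scale))
    nw, nh = min(nw, cw), min(nh, ch)
    if (nw, nh) == (w, h):
        content = image.astype(float, copy=False)
    else:
        content = _sk_resize(
            image.astype(float), (nh, nw), order=1, anti_aliasing=False,
            preserve_range=True,
        )
    pad_x = (cw - nw) // 2
    pad_y = (ch - nh) // 2
    out = np.zeros((ch, cw), dtype=float)
    out[pad_y : pad_y + nh, pad_x : pad_x + nw] = content
    if np.issubdtype(image.dtype, np.integer):
        out = np.rint(out).astype(image.dtype)
    t = CanvasTransform(
        scale=scale,
        pad_x=float(pad_x),
        pad_y=float(pad_y),
        original_size=(w, h),
        canvas_size=(cw, ch),
    )
    return out, t


def clahe_enhance(
    image: np.ndarray, clip_limit: float = 2.0, tile_grid: Tuple[int, int] = (8, 8)
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    ``clip_limit`` follows the common histogram-multiple convention (2.0 by
    default) and ``tile_grid`` the number of tiles per axis; internally the
    clip limit is renormalized to the bin-fraction convention of
    ``skimage.exposure.equalize_adapthist``.  Output keeps the input shape
    and dtype range; a constant image passes through unchanged.
    """
    from skimage import exposure

    if image.ndim != 2:
        raise ValueError(f"CLAHE expects a 2-D grayscale image, got {image.shape}")
    arr = np.asarray(image)
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo <= 0:
        return arr.copy()
    nbins = 256
    norm = (arr.astype(float) - lo) / (hi - lo)
    kernel = (
        max(1, arr.shape[0] // tile_grid[1]),
        max(1, arr.shape[1] // tile_grid[0]),
    )
    eq = exposure.equalize_adapthist(
        norm, kernel_size=kernel, clip_limit=clip_limit / nbins, nbins=nbins
    )
    out = eq * (hi - lo) + lo
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(arr.dtype)
    return out


def map_landmarks(
    points: Sequence[Point2D], transform: CanvasTransform, direction: str = "to_canvas"
):
    """Map a sequence of points through the canvas transform.

    ``direction`` is ``"to_canvas"`` or ``"to_original"``; the latter raises
    :class:`PaddedRegionError` for points in the zero-padded margin.
    """
    if direction == "to_canvas":
        return [transform.to_canvas(Point2D.of(p)) for p in points]
    if direction == "to_original":
        return [transform.to_original(Point2D.of(p)) for p in points]
    raise ValueError(f"direction must be to_canvas or to_original, got {direction!r}")
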