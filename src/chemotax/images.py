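"""Reading, writing and debug rendering of plate images.

All pipeline stages operate on :class:`GrayscaleImage`, a thin wrapper
around a float64 array with intensities normalized to [0, 1].  8- and
16-bit integer inputs are rescaled by their dtype maximum; RGB inputs are
converted by Rec. 709 luminance weighting.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

from .errors import ImageIOError, ValidationError

MIN_DIM = 64

_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass(frozen=True)
class GrayscaleImage:
    """A single-plate grayscale photograph with intensities in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 2:
            raise ValidationError(f"expected a 2-D array, got shape {px.shape}")
        if px.shape[0] < MIN_DIM or px.shape[1] < MIN_DIM:
            raise ValidationError(
                f"image too small ({px.shape[0]}x{px.shape[1]}); "
                f"need at least {MIN_DIM}x{MIN_DIM}"
            )
        if not np.isfinite(px).all():
            raise ValidationError("image contains non-finite values")
        if px.min() < 0 or px.max() > 1:
            raise ValidationError("image intensities must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _normalize(raw: np.ndarray) -> np.ndarray:
    if raw.dtype == np.uint8:
        return raw.astype(np.float64) / 255.0
    if raw.dtype == np.uint16:
        return raw.astype(np.float64) / 65535.0
    if np.issubdtype(raw.dtype, np.integer):
        info = np.iinfo(raw.dtype)
        return raw.astype(np.float64) / float(info.max)
    return np.clip(raw.astype(np.float64), 0.0, 1.0)


def load_image(path: str | os.PathLike) -> GrayscaleImage:
    """Read a PNG/TIFF/JPEG plate photograph as a normalized grayscale image.

    RGB(A) images are converted by luminance weighting; 8/16-bit depths
    are handled transparently.

    Raises
    ------
    ImageIOError
        If the file is missing, truncated or otherwise unreadable.
    ValidationError
        If the decoded image is empty or too small.
    """
    try:
        raw = iio.imread(path)
    # decoders raise a grab-bag of exception types on corrupt input
    # (PIL uses SyntaxError for broken PNG streams)
    except (OSError, ValueError, SyntaxError, RuntimeError) as exc:
        raise ImageIOError(f"cannot read image {os.fspath(path)!r}: {exc}") from exc
    if raw.size == 0:
        raise ValidationError(f"zero-sized image: {os.fspath(path)!r}")
    arr = _normalize(np.asarray(raw))
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
        arr = np.clip(arr, 0.0, 1.0)
    return GrayscaleImage(pixels=arr)


def write_debug_image(image: GrayscaleImage | np.ndarray, path: str | os.PathLike) -> None:
    """Write an image (grayscale in [0,1] or uint8 RGB overlay) as lossless PNG."""
    if isinstance(image, GrayscaleImage):
        arr = image.pixels
    else:
        arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    parent = os.path.dirname(os.fspath(path))
    if parent:
        os.makedirs(parent, exist_ok=True)
    try:
        iio.imwrite(path, arr, extension=".png")
    except OSError as exc:
        raise ImageIOError(f"cannot write image {os.fspath(path)!r}: {exc}") from exc


def render_overlay(
    image: GrayscaleImage,
    geometry=None,
    kept_mask: np.ndarray | None = None,
    filtered_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Render a debug overlay: geometry lines plus kept/filtered objects.

    The plate circle, quadrant boundary axes and center-exclusion circle
    are drawn in yellow/blue; kept nematode pixels in green, filtered
    (non-nematode) pixels in red.  Returns an RGB uint8 array.
    """
    base = np.round(image.pixels * 255.0).astype(np.uint8)
    rgb = np.stack([base, base, base], axis=-1)
    if kept_mask is not None and kept_mask.any():
        rgb[kept_mask.astype(bool)] = (0, 200, 0)
    if filtered_mask is not None and filtered_mask.any():
        rgb[filtered_mask.astype(bool)] = (220, 0, 0)
    if geometry is not None:
        h, w = image.shape
        rows = np.arange(h, dtype=np.float64)[:, None] - geometry.center[0]
        cols = np.arange(w, dtype=np.float64)[None, :] - geometry.center[1]
        dist = np.hypot(rows, cols)
        for radius, color in (
            (geometry.radius, (255, 220, 0)),
            (geometry.scoring_radius, (255, 160, 0)),
            (geometry.center_radius, (80, 120, 255)),
        ):
            ring = np.abs(dist - radius) <= 0.75
            rgb[ring] = color
        # quadrant separator axes
        ang = np.radians(geometry.axis_rotation_deg)
        u = np.array([-np.sin(ang), np.cos(ang)])   # axis at rotation_deg
        v = np.array([-np.cos(ang), -np.sin(ang)])  # perpendicular axis
        inside = dist <= geometry.scoring_radius
        # distance of each pixel to each axis line through the center
        d1 = np.abs(rows * u[1] - cols * u[0])
        d2 = np.abs(rows * v[1] - cols * v[0])
        rgb[(d1 <= 0.5) & inside] = (80, 120, 255)
        rgb[(d2 <= 0.5) & inside] = (80, 120, 255)
    return rgb
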