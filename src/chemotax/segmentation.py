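"""Foreground segmentation and non-nematode object filtering.

The segmentation stage separates nematode objects from the agar
background inside the detected plate and removes objects that are not
nematodes (debris specks, plate-scale artifacts, and the hollow ring left
by an unabsorbed test spot), reporting exactly how many foreground pixels
were filtered out.  Clumped animals are deliberately NOT split into
individuals: the downstream score uses pixel area as a proxy for counts,
so a clump simply contributes its full area.

Polarity convention: internally the pipeline works on images with dark
worms on a lighter agar.  Images with the opposite polarity are inverted
up front, which makes the light/dark configurations exactly symmetric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .errors import ValidationError
from .geometry import PlateGeometry
from .images import GrayscaleImage


@dataclass(frozen=True)
class SegmentationConfig:
    """Segmentation and filtering parameters.

    ``expected_worm_area_px`` anchors the object-size filters: components
    below ``min_area_frac`` of it are debris, components above
    ``max_area_frac`` of it are plate-scale artifacts (large clumps stay
    well below that ceiling).  The default of 120 px matches a rig where
    a single L4 animal covers roughly that many pixels; rescale it when
    the imaging scale differs.
    """

    polarity: str = "dark"            # which side of the threshold is worm
    threshold_method: str = "otsu"    # "otsu" or "fixed"
    fixed_threshold: float | None = None
    expected_worm_area_px: float = 120.0
    min_area_frac: float = 0.2
    max_area_frac: float = 50.0
    min_area_px: float | None = None  # override the fractional defaults
    max_area_px: float | None = None
    ring_filter: bool = True
    ring_shape_ratio: float = 30.0    # perimeter^2/area above this is thin
    ring_hollow_ratio: float = 1.5    # filled_area/area above this is hollow
    min_contrast: float = 0.1         # required Otsu class separation
    closing_width_px: int = 9         # grey-closing window for background
    background_sigma_frac: float = 0.06   # blur sigma as fraction of radius

    def __post_init__(self) -> None:
        if self.polarity not in ("dark", "light"):
            raise ValidationError(f"polarity must be 'dark' or 'light', got {self.polarity!r}")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValidationError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValidationError("fixed threshold method requires fixed_threshold")

    @property
    def effective_min_area(self) -> float:
        if self.min_area_px is not None:
            return self.min_area_px
        return self.min_area_frac * self.expected_worm_area_px

    @property
    def effective_max_area(self) -> float:
        if self.max_area_px is not None:
            return self.max_area_px
        return self.max_area_frac * self.expected_worm_area_px


@dataclass(frozen=True)
class ObjectStats:
    """Shape summary of one kept component."""

    area: int
    bbox: tuple[int, int, int, int]
    elongation: float  # eccentricity of the equivalent ellipse, in [0, 1)


@dataclass(frozen=True)
class SegmentationResult:
    """Kept nematode mask plus the count of filtered foreground pixels."""

    mask: np.ndarray = field(repr=False)
    filtered_pixels: int
    objects: tuple[ObjectStats, ...] = ()

    @property
    def kept_pixels(self) -> int:
        return int(self.mask.sum())


def _plate_mask(geometry: PlateGeometry, shape: tuple[int, int]) -> np.ndarray:
    rows = np.arange(shape[0], dtype=np.float64)[:, None] - geometry.center[0]
    cols = np.arange(shape[1], dtype=np.float64)[None, :] - geometry.center[1]
    return np.hypot(rows, cols) <= geometry.scoring_radius


def _canonical(image: GrayscaleImage, config: SegmentationConfig) -> np.ndarray:
    px = image.pixels
    return 1.0 - px if config.polarity == "light" else px


def preprocess(
    image: GrayscaleImage,
    geometry: PlateGeometry,
    config: SegmentationConfig | None = None,
) -> GrayscaleImage:
    """Flatten the illumination gradient inside the plate.

    The large-scale background is estimated by a grey-value closing (which
    removes the thin dark worms) followed by a heavy Gaussian blur, and
    subtracted; the result is re-centered at 0.5 so a perfectly flat plate
    maps to a constant 0.5.  Output polarity is canonical (worms dark)
    regardless of the configured input polarity.
    """
    cfg = config or SegmentationConfig()
    px = _canonical(image, cfg)
    inside = _plate_mask(geometry, px.shape)
    if not inside.any():
        raise ValidationError("plate geometry covers no pixels of the image")
    # extend the plate interior outward by nearest-neighbour values so the
    # morphological window never mixes in background or fill intensities
    _, (ir, ic) = ndi.distance_transform_edt(~inside, return_indices=True)
    work = px[ir, ic]
    closed = ndi.grey_closing(work, size=cfg.closing_width_px)
    sigma = max(1.0, cfg.background_sigma_frac * geometry.radius)
    # normalized convolution: average over plate-interior pixels only, so
    # the background estimate is unbiased near the plate wall
    weight = inside.astype(np.float64)
    num = ndi.gaussian_filter(closed * weight, sigma=sigma)
    den = ndi.gaussian_filter(weight, sigma=sigma)
    background = np.divide(num, den, out=np.full_like(num, px[inside].mean()),
                           where=den > 1e-12)
    corrected = np.clip(px - background + 0.5, 0.0, 1.0)
    corrected[~inside] = 0.5
    return GrayscaleImage(pixels=corrected)


def segment_foreground(
    image: GrayscaleImage,
    geometry: PlateGeometry,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Threshold the (preprocessed) plate interior into a foreground mask.

    An automatic Otsu threshold is computed over plate-interior pixels
    only; pixels darker than the threshold become foreground.  If the
    interior histogram is degenerate, or the two Otsu classes are closer
    than ``min_contrast`` (nothing worm-like on the plate), an empty mask
    is returned with a warning rather than an exception.  The mask is
    forced to zero outside the trimmed plate.
    """
    cfg = config or SegmentationConfig()
    px = image.pixels  # preprocess() already canonicalised polarity
    inside = _plate_mask(geometry, px.shape)
    values = px[inside]
    empty = np.zeros(px.shape, dtype=bool)
    if cfg.threshold_method == "fixed":
        t = float(cfg.fixed_threshold)
    else:
        if float(values.max() - values.min()) < 1e-6:
            warnings.warn("degenerate plate-interior histogram; empty mask")
            return empty
        t = float(threshold_otsu(values))
        fg_vals = values[values < t]
        bg_vals = values[values >= t]
        if fg_vals.size == 0 or bg_vals.size == 0:
            warnings.warn("Otsu produced a one-sided split; empty mask")
            return empty
        if float(bg_vals.mean() - fg_vals.mean()) < cfg.min_contrast:
            warnings.warn(
                "foreground/background contrast below the confidence floor; "
                "treating the plate as empty"
            )
            return empty
    return (px < t) & inside


def filter_objects(
    mask: np.ndarray,
    geometry: PlateGeometry,
    config: SegmentationConfig | None = None,
) -> SegmentationResult:
    """Remove non-nematode connected components from a foreground mask.

    Components (8-connectivity) are dropped when their area falls below
    ``min_area`` (debris specks) or above ``max_area`` (plate-scale
    artifacts), or when the thin-ring score — a high perimeter²/area
    combined with a hollow interior — marks them as the edge of an
    unabsorbed test spot.  Clumps of animals are kept whole.  The exact
    number of removed pixels is reported so that kept + filtered equals
    the thresholded foreground.
    """
    cfg = config or SegmentationConfig()
    mask = np.asarray(mask).astype(bool)
    total = int(mask.sum())
    if total == 0:
        return SegmentationResult(mask=mask.copy(), filtered_pixels=0, objects=())

    labels = cc_label(mask, connectivity=2)
    kept = np.zeros_like(mask)
    objects: list[ObjectStats] = []
    min_area = cfg.effective_min_area
    max_area = cfg.effective_max_area
    for prop in regionprops(labels):
        area = int(prop.area)
        if area < min_area or area > max_area:
            continue
        if cfg.ring_filter and area > 0:
            shape_ratio = prop.perimeter**2 / area if prop.perimeter > 0 else 0.0
            hollow_ratio = prop.area_filled / area
            if shape_ratio > cfg.ring_shape_ratio and hollow_ratio > cfg.ring_hollow_ratio:
                continue
        kept[labels == prop.label] = True
        objects.append(
            ObjectStats(area=area, bbox=tuple(prop.bbox), elongation=float(prop.eccentricity))
        )
    return SegmentationResult(
        mask=kept,
        filtered_pixels=total - int(kept.sum()),
        objects=tuple(objects),
    )
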