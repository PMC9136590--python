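"""Plate-circle detection and quadrant / center-exclusion region maps.

A quadrant chemotaxis plate is scored over four sectors of the detected
plate disk.  A margin fraction of the radius is trimmed at the plate wall
(meniscus and wall reflections), and a central disk — where the animals
were dispensed — is excluded from scoring.  Quadrants are numbered 1-4
counter-clockwise starting from the upper-right sector, with an optional
rotation of the separating axes relative to the image axes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import PlateDetectionError, ValidationError
from .images import GrayscaleImage

# Region codes used in RegionLabelMap.labels
OUTSIDE = 0
Q1, Q2, Q3, Q4 = 1, 2, 3, 4
CENTER = 5

QUADRANTS = (Q1, Q2, Q3, Q4)

#: Diagonal quadrant pairs that may carry the test compound.
DIAGONAL_PAIRS = ((1, 3), (2, 4))


@dataclass(frozen=True)
class PlateGeometry:
    """Detected (or manually supplied) plate circle plus scoring layout.

    Parameters
    ----------
    center
        Sub-pixel ``(row, col)`` coordinates of the plate center.
    radius
        Plate radius in pixels.
    margin_frac
        Fraction of the radius trimmed at the plate wall; pixels beyond
        ``(1 - margin_frac) * radius`` are not scored.
    center_exclusion_frac
        Fraction of the radius defining the origin zone; animals that
        never left this disk are excluded from the CI denominator.
    axis_rotation_deg
        Rotation of the quadrant axes counter-clockwise relative to the
        image axes (degrees).
    """

    center: tuple[float, float]
    radius: float
    margin_frac: float = 0.05
    center_exclusion_frac: float = 0.15
    axis_rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValidationError(f"radius must be positive, got {self.radius}")
        if not 0 <= self.margin_frac < 0.5:
            raise ValidationError(
                f"margin_frac must be in [0, 0.5), got {self.margin_frac}"
            )
        if not 0 < self.center_exclusion_frac < 1 - self.margin_frac:
            raise ValidationError(
                "center_exclusion_frac must lie in (0, 1 - margin_frac), "
                f"got {self.center_exclusion_frac}"
            )

    @property
    def scoring_radius(self) -> float:
        """Radius of the scored disk after trimming the wall margin."""
        return (1.0 - self.margin_frac) * self.radius

    @property
    def center_radius(self) -> float:
        """Radius of the excluded origin zone."""
        return self.center_exclusion_frac * self.radius

    def translated(self, drow: float, dcol: float) -> "PlateGeometry":
        return replace(self, center=(self.center[0] + drow, self.center[1] + dcol))


@dataclass(frozen=True)
class RegionLabelMap:
    """Per-pixel region codes for one plate image.

    ``labels`` holds one of {OUTSIDE, Q1..Q4, CENTER} per pixel; the union
    of Q1-Q4 and CENTER is exactly the trimmed plate disk.
    """

    labels: np.ndarray
    geometry: PlateGeometry

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def region_counts(self) -> dict[int, int]:
        counts = np.bincount(self.labels.ravel(), minlength=6)
        return {code: int(counts[code]) for code in range(6)}


def build_region_map(geometry: PlateGeometry, shape: tuple[int, int]) -> RegionLabelMap:
    """Construct the quadrant + center-exclusion label map for ``shape``.

    Quadrants are delimited by two perpendicular lines through the plate
    center at ``axis_rotation_deg``; pixels exactly on a boundary are
    assigned by half-open angular intervals [0°, 90°), [90°, 180°), ... so
    every pixel receives exactly one code.
    """
    h, w = shape
    cr, cc = geometry.center
    r_score = geometry.scoring_radius
    if (
        cr - r_score < -0.5
        or cc - r_score < -0.5
        or cr + r_score > h - 0.5
        or cc + r_score > w - 0.5
    ):
        raise ValidationError(
            "trimmed plate circle extends outside the image bounds: "
            f"center={geometry.center}, scoring radius={r_score:.1f}, shape={shape}"
        )

    rows = np.arange(h, dtype=np.float64)[:, None] - cr
    cols = np.arange(w, dtype=np.float64)[None, :] - cc
    dist = np.hypot(rows, cols)
    # image rows grow downward; negate to get mathematical y-up angles
    theta = np.degrees(np.arctan2(-rows, cols)) - geometry.axis_rotation_deg
    theta = np.mod(theta, 360.0)
    quadrant = (theta // 90.0).astype(np.int32) + 1

    labels = quadrant
    labels = np.where(dist <= geometry.center_radius, CENTER, labels)
    labels = np.where(dist > r_score, OUTSIDE, labels)
    return RegionLabelMap(labels=labels.astype(np.int32), geometry=geometry)


@dataclass(frozen=True)
class DetectionConfig:
    """Tunables for :func:`detect_plate`.

    ``min/max_radius_frac`` bound the plausible plate radius as a fraction
    of the smaller image dimension; ``max_residual_frac`` is the maximum
    RMS deviation of boundary pixels from the fitted circle, relative to
    the radius, accepted as a confident detection.
    """

    min_radius_frac: float = 0.15
    max_radius_frac: float = 0.75
    max_residual_frac: float = 0.05
    min_intensity_range: float = 0.05
    margin_frac: float = 0.05
    center_exclusion_frac: float = 0.15
    axis_rotation_deg: float = 0.0


def _fit_circle(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float, float, float]:
    """Algebraic (Kasa) least-squares circle fit.

    Returns (center_row, center_col, radius, rms_residual).
    """
    a = np.column_stack([rows, cols, np.ones_like(rows)])
    b = rows**2 + cols**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cr, cc = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cr**2 + cc**2
    if r2 <= 0:
        raise PlateDetectionError("degenerate circle fit")
    radius = float(np.sqrt(r2))
    resid = np.hypot(rows - cr, cols - cc) - radius
    return float(cr), float(cc), radius, float(np.sqrt(np.mean(resid**2)))


def _boundary_candidates(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    filled = ndi.binary_fill_holes(mask)
    boundary = filled & ~ndi.binary_erosion(filled, border_value=0)
    return np.nonzero(boundary)


def detect_plate(
    image: GrayscaleImage, config: DetectionConfig | None = None
) -> PlateGeometry:
    """Locate the circular plate boundary in a raw image.

    Strategy: Otsu threshold -> largest connected bright region -> fill
    holes -> least-squares circle fit to the region boundary.  If the
    bright-region fit is rejected (radius out of range or poor residual),
    the inverted (dark plate on light background) hypothesis is tried.

    Raises
    ------
    PlateDetectionError
        If no circle passes the confidence checks; the message suggests
        the manual geometry override.
    """
    cfg = config or DetectionConfig()
    px = image.pixels
    h, w = px.shape
    if float(px.max() - px.min()) < cfg.min_intensity_range:
        raise PlateDetectionError(
            "image has no plate/background contrast; supply geometry manually "
            "(--center/--radius)"
        )

    t = threshold_otsu(px)
    min_r = cfg.min_radius_frac * min(h, w)
    max_r = cfg.max_radius_frac * min(h, w)

    best: tuple[float, float, float, float] | None = None
    for mask in (px > t, px < t):
        if not mask.any():
            continue
        lab = cc_label(mask, connectivity=2)
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        component = lab == int(np.argmax(sizes))
        rr, cc_ = _boundary_candidates(component)
        if rr.size < 16:
            continue
        try:
            cr, cc0, radius, rms = _fit_circle(
                rr.astype(np.float64), cc_.astype(np.float64)
            )
        except PlateDetectionError:
            continue
        if not (min_r <= radius <= max_r):
            continue
        if rms / radius > cfg.max_residual_frac:
            continue
        if not (0 <= cr < h and 0 <= cc0 < w):
            continue
        if best is None or rms < best[3]:
            best = (cr, cc0, radius, rms)

    if best is None:
        raise PlateDetectionError(
            "no circular plate boundary found above the confidence floor; "
            "supply geometry manually (--center/--radius)"
        )

    cr, cc0, radius, _ = best
    return PlateGeometry(
        center=(cr, cc0),
        radius=radius,
        margin_frac=cfg.margin_frac,
        center_exclusion_frac=cfg.center_exclusion_frac,
        axis_rotation_deg=cfg.axis_rotation_deg,
    )
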