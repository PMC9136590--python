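"""Synthetic quadrant-assay plate images with exact ground truth.

The generator emulates a photograph of a single 6 cm assay plate: a bright
circular plate on a dark background with a radial-quadratic illumination
falloff (vignette), worm-shaped foreground blobs of known pixel area
placed at known quadrant positions, optional debris specks below worm
size, and an optional ring artifact emulating the reflective edge of an
unabsorbed test-compound spot.  Every blob is placed fully inside its
assigned region (outside the center-exclusion zone, inside the trimmed
plate margin, clear of quadrant boundaries), so the rendered foreground
pixel counts per region are known exactly and the true chemotaxis index
of the plate is available for benchmarking the full pipeline.

Worm blobs are thick random-walk curves rather than discs so that
shape-based filtering is exercised realistically.  All randomness comes
from a single seeded generator per call; identical spec + seed yields a
bit-identical image and ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from .errors import CapacityError, ValidationError
from .geometry import CENTER, PlateGeometry, RegionLabelMap, build_region_map
from .images import GrayscaleImage
from .scoring import QuadrantAreas, compute_ci

_MAX_TRIES = 2000
_REDRAW_EVERY = 100
_PLACEMENT_BUFFER = 4.0   # px clearance from region boundaries
_SEPARATION = 2           # px dilation separating placed objects

_BACKGROUND = 0.08
_PLATE_PEAK = 0.85
_FOREGROUND_DROP = 0.55
_FOREGROUND_FLOOR = 0.05

#: worm aspect ratio (length : width) used to size the blob stroke
_ASPECT = 13.0


@dataclass(frozen=True)
class SpotRing:
    """Ring artifact at a test-spot location: the bright/dark rim of an
    unabsorbed compound droplet, a known false-positive for segmentation."""

    quadrant: int = 1
    radius: float = 28.0
    thickness: float = 3.0

    def __post_init__(self) -> None:
        if self.quadrant not in (1, 2, 3, 4):
            raise ValidationError(f"quadrant must be 1-4, got {self.quadrant}")
        if self.radius <= 0 or self.thickness <= 0:
            raise ValidationError("ring radius and thickness must be positive")


@dataclass(frozen=True)
class SyntheticPlateSpec:
    """Parameters of one synthetic plate image.

    Quadrants are numbered 1-4 counter-clockwise from upper-right.  The
    defaults model a plate photographed at a scale where a single L4 worm
    covers about 120 px.
    """

    image_size: int = 768
    plate_center: tuple[float, float] | None = None
    plate_radius: float = 300.0
    foreground_polarity: str = "dark_on_light"
    worms_per_quadrant: tuple[int, int, int, int] = (12, 13, 12, 13)
    worm_area_px: int = 120
    center_worms: int = 0
    clumps_per_quadrant: tuple[int, int, int, int] = (0, 0, 0, 0)
    clump_size: int = 3
    debris_count: int = 0
    debris_area_px: int = 3
    blur_sigma: float = 0.7
    spot_ring: SpotRing | None = None
    vignette_strength: float = 0.3
    noise_sd: float = 0.01
    margin_frac: float = 0.05
    center_exclusion_frac: float = 0.15
    axis_rotation_deg: float = 0.0
    test_pair: tuple[int, int] = (1, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.foreground_polarity not in ("dark_on_light", "light_on_dark"):
            raise ValidationError(
                f"unknown foreground_polarity {self.foreground_polarity!r}"
            )
        if self.worm_area_px < 4:
            raise ValidationError("worm_area_px must be >= 4")
        if len(self.worms_per_quadrant) != 4 or any(
            n < 0 for n in self.worms_per_quadrant
        ):
            raise ValidationError("worms_per_quadrant must be 4 non-negative counts")
        if self.center_worms < 0 or self.debris_count < 0:
            raise ValidationError("object counts must be non-negative")
        if len(self.clumps_per_quadrant) != 4 or any(
            n < 0 for n in self.clumps_per_quadrant
        ):
            raise ValidationError("clumps_per_quadrant must be 4 non-negative counts")
        if self.clump_size < 2:
            raise ValidationError("clump_size must be >= 2 worms")
        if self.blur_sigma < 0:
            raise ValidationError("blur_sigma must be non-negative")
        if not 0 <= self.vignette_strength <= 1:
            raise ValidationError("vignette_strength must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        cr, cc = self.center
        r = self.plate_radius
        n = self.image_size
        if cr - r < 0 or cc - r < 0 or cr + r > n - 1 or cc + r > n - 1:
            raise ValidationError("plate circle must lie fully inside the image")

    @property
    def center(self) -> tuple[float, float]:
        if self.plate_center is not None:
            return self.plate_center
        c = (self.image_size - 1) / 2.0
        return (c, c)

    def geometry(self) -> PlateGeometry:
        return PlateGeometry(
            center=self.center,
            radius=self.plate_radius,
            margin_frac=self.margin_frac,
            center_exclusion_frac=self.center_exclusion_frac,
            axis_rotation_deg=self.axis_rotation_deg,
        )


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Exact rendered truth for one generated plate."""

    true_geometry: PlateGeometry
    true_area_per_quadrant: tuple[int, int, int, int]
    true_center_area: int
    true_debris_pixels: int
    test_pair: tuple[int, int]
    true_ci: float | None
    worm_mask: np.ndarray = field(repr=False)
    artifact_mask: np.ndarray = field(repr=False)

    @property
    def total_foreground_pixels(self) -> int:
        return (
            sum(self.true_area_per_quadrant)
            + self.true_center_area
            + self.true_debris_pixels
        )

    def quadrant_areas(self) -> QuadrantAreas:
        q1, q2, q3, q4 = self.true_area_per_quadrant
        return QuadrantAreas(q1=q1, q2=q2, q3=q3, q4=q4, center_px=self.true_center_area)


def _worm_patch(rng: np.random.Generator, area_px: int) -> np.ndarray:
    """Render one worm blob as a thick random-walk curve in a local patch."""
    width = max(2.0, np.sqrt(area_px / _ASPECT))
    stamp_r = width / 2.0 + 0.5
    # patch comfortably larger than the expected worm length sqrt(area*aspect)
    size = int(2.0 * np.sqrt(area_px * _ASPECT)) + 16
    patch = np.zeros((size, size), dtype=bool)
    pos = np.array([size / 2.0, size / 2.0])
    heading = rng.uniform(0.0, 2.0 * np.pi)
    while patch.sum() < area_px:
        pos = pos + np.array([-np.sin(heading), np.cos(heading)])
        heading += rng.normal(0.0, 0.25)
        # steer back toward the patch center when close to the border
        margin = stamp_r + 2.0
        if (
            pos[0] < margin
            or pos[1] < margin
            or pos[0] > size - 1 - margin
            or pos[1] > size - 1 - margin
        ):
            to_center = np.arctan2(
                -(size / 2.0 - pos[0]), size / 2.0 - pos[1]
            )
            heading = to_center + rng.normal(0.0, 0.2)
            continue
        rr, cc = draw_disk((pos[0], pos[1]), stamp_r, shape=patch.shape)
        patch[rr, cc] = True
    rows, cols = np.nonzero(patch)
    r0, c0 = rows.min(), cols.min()
    out = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=bool)
    out[rows - r0, cols - c0] = True
    return out


def _clump_patch(rng: np.random.Generator, area_px: int, n_worms: int) -> np.ndarray:
    """Several worms overlaid with small offsets: one tightly clumped blob."""
    worms = [_worm_patch(rng, area_px) for _ in range(n_worms)]
    side = max(max(w.shape) for w in worms) + 8
    patch = np.zeros((side * 2, side * 2), dtype=bool)
    anchor = np.array([side, side])
    for w in worms:
        off = anchor + rng.integers(-4, 5, size=2) - np.array(w.shape) // 2
        r0 = int(np.clip(off[0], 0, patch.shape[0] - w.shape[0]))
        c0 = int(np.clip(off[1], 0, patch.shape[1] - w.shape[1]))
        patch[r0 : r0 + w.shape[0], c0 : c0 + w.shape[1]] |= w
    from scipy import ndimage as ndi

    # keep only the component touching the anchor region, so the clump is
    # one connected object
    lab, _ = ndi.label(patch, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    patch = lab == int(np.argmax(sizes))
    rows, cols = np.nonzero(patch)
    r0, c0 = rows.min(), cols.min()
    out = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=bool)
    out[rows - r0, cols - c0] = True
    return out


def _speck_patch(rng: np.random.Generator, area_px: int) -> np.ndarray:
    """A debris speck: ``area_px`` 4-connected pixels grown from a seed."""
    size = area_px + 2
    patch = np.zeros((size, size), dtype=bool)
    r = c = size // 2
    patch[r, c] = True
    while patch.sum() < area_px:
        rows, cols = np.nonzero(patch)
        i = rng.integers(rows.size)
        dr, dc = ((-1, 0), (1, 0), (0, -1), (0, 1))[rng.integers(4)]
        rr, cc = int(rows[i]) + dr, int(cols[i]) + dc
        if 0 <= rr < size and 0 <= cc < size:
            patch[rr, cc] = True
    rows, cols = np.nonzero(patch)
    r0, c0 = rows.min(), cols.min()
    out = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=bool)
    out[rows - r0, cols - c0] = True
    return out


class _Placer:
    """Collision-free placement of blob patches into labelled plate regions."""

    def __init__(self, regions: RegionLabelMap):
        geo = regions.geometry
        h, w = regions.shape
        self.labels = regions.labels
        self.geo = geo
        rows = np.arange(h, dtype=np.float64)[:, None] - geo.center[0]
        cols = np.arange(w, dtype=np.float64)[None, :] - geo.center[1]
        self.dist = np.hypot(rows, cols)
        ang = np.radians(geo.axis_rotation_deg)
        u = (-np.sin(ang), np.cos(ang))
        v = (-np.cos(ang), -np.sin(ang))
        # unsigned distance to each quadrant separator line
        self.axis_dist = np.minimum(
            np.abs(rows * u[1] - cols * u[0]),
            np.abs(rows * v[1] - cols * v[0]),
        )
        self.occupied = np.zeros((h, w), dtype=bool)
        self.shape = (h, w)

    def block(self, mask: np.ndarray) -> None:
        from scipy import ndimage as ndi

        self.occupied |= ndi.binary_dilation(mask, iterations=_SEPARATION)

    @staticmethod
    def _prepare(patch: np.ndarray):
        from scipy import ndimage as ndi

        prow, pcol = np.nonzero(patch)
        dil = ndi.binary_dilation(
            np.pad(patch, _SEPARATION), iterations=_SEPARATION
        )
        drow, dcol = np.nonzero(dil)
        return patch.shape, prow, pcol, drow - _SEPARATION, dcol - _SEPARATION

    def place(
        self,
        rng: np.random.Generator,
        make_patch,
        target_code: int,
        out_mask: np.ndarray,
        buffer: float = _PLACEMENT_BUFFER,
    ) -> None:
        """Place one blob from ``make_patch()`` into the target region.

        The blob shape is re-drawn every ``_REDRAW_EVERY`` failed tries: a
        particular random shape may be too extended to fit the region (the
        center disk especially) even though some shape of the same area
        does.
        """
        (bh, bw), prow, pcol, drow, dcol = self._prepare(make_patch())
        h, w = self.shape
        cr, cc = self.geo.center
        geo = self.geo
        for attempt in range(_MAX_TRIES):
            if attempt and attempt % _REDRAW_EVERY == 0:
                (bh, bw), prow, pcol, drow, dcol = self._prepare(make_patch())
            # sample the blob center directly inside the target region:
            # uniformly over the center disk, or over the quadrant's
            # angular wedge of the scoring annulus
            if target_code == CENTER:
                rad = geo.center_radius * np.sqrt(rng.uniform())
                ang = rng.uniform(0.0, 360.0)
            else:
                r_lo = geo.center_radius + buffer
                r_hi = geo.scoring_radius - buffer
                if r_hi <= r_lo:
                    raise CapacityError("scoring annulus too thin for placement")
                rad = np.sqrt(rng.uniform(r_lo**2, r_hi**2))
                ang = geo.axis_rotation_deg + 90.0 * (target_code - 1) + rng.uniform(
                    0.0, 90.0
                )
            mid_r = cr - rad * np.sin(np.radians(ang))
            mid_c = cc + rad * np.cos(np.radians(ang))
            r0 = int(round(mid_r - bh / 2.0))
            c0 = int(round(mid_c - bw / 2.0))
            if r0 < 0 or c0 < 0 or r0 + bh > h or c0 + bw > w:
                continue
            ar, ac = prow + r0, pcol + c0
            if self.labels[ar, ac].min() != target_code or (
                self.labels[ar, ac].max() != target_code
            ):
                continue
            d = self.dist[ar, ac]
            if target_code == CENTER:
                if d.max() > self.geo.center_radius - buffer:
                    continue
            else:
                if (
                    d.min() < self.geo.center_radius + buffer
                    or d.max() > self.geo.scoring_radius - buffer
                    or self.axis_dist[ar, ac].min() < buffer
                ):
                    continue
            gr, gc = drow + r0, dcol + c0
            inb = (gr >= 0) & (gr < h) & (gc >= 0) & (gc < w)
            if self.occupied[gr[inb], gc[inb]].any():
                continue
            out_mask[ar, ac] = True
            self.occupied[gr[inb], gc[inb]] = True
            return
        raise CapacityError(
            f"could not place a blob in region {target_code} after "
            f"{_MAX_TRIES} tries; reduce object counts or areas"
        )


def _ring_mask(spec: SyntheticPlateSpec, placer: _Placer) -> np.ndarray:
    ring = spec.spot_ring
    assert ring is not None
    geo = placer.geo
    mid = geo.axis_rotation_deg + 90.0 * (ring.quadrant - 1) + 45.0
    r_pos = (geo.center_radius + geo.scoring_radius) / 2.0
    ctr = (
        geo.center[0] - r_pos * np.sin(np.radians(mid)),
        geo.center[1] + r_pos * np.cos(np.radians(mid)),
    )
    h, w = placer.shape
    rows = np.arange(h, dtype=np.float64)[:, None] - ctr[0]
    cols = np.arange(w, dtype=np.float64)[None, :] - ctr[1]
    d = np.hypot(rows, cols)
    mask = np.abs(d - ring.radius) <= ring.thickness / 2.0
    mask &= placer.dist <= geo.scoring_radius
    return mask


def generate_synthetic_plate(
    spec: SyntheticPlateSpec,
) -> tuple[GrayscaleImage, SyntheticGroundTruth]:
    """Render one plate image and its exact ground truth.

    Deterministic for a fixed spec (the seed lives in the spec).  Raises
    :class:`CapacityError` if the requested blobs cannot be placed without
    overlap within a bounded number of retries.
    """
    rng = np.random.default_rng(spec.seed)
    geometry = spec.geometry()
    shape = (spec.image_size, spec.image_size)
    regions = build_region_map(geometry, shape)
    placer = _Placer(regions)

    artifact_mask = np.zeros(shape, dtype=bool)
    worm_mask = np.zeros(shape, dtype=bool)

    # ring first so worms are placed clear of it and the ring stays closed
    if spec.spot_ring is not None:
        ring = _ring_mask(spec, placer)
        artifact_mask |= ring
        placer.block(ring)

    worm = lambda: _worm_patch(rng, spec.worm_area_px)  # noqa: E731
    clump = lambda: _clump_patch(rng, spec.worm_area_px, spec.clump_size)  # noqa: E731
    for q, n_worms in enumerate(spec.worms_per_quadrant, start=1):
        for _ in range(n_worms):
            placer.place(rng, worm, q, worm_mask)
    for q, n_clumps in enumerate(spec.clumps_per_quadrant, start=1):
        for _ in range(n_clumps):
            placer.place(rng, clump, q, worm_mask)
    for _ in range(spec.center_worms):
        placer.place(rng, worm, CENTER, worm_mask)

    debris_mask = np.zeros(shape, dtype=bool)
    speck = lambda: _speck_patch(rng, spec.debris_area_px)  # noqa: E731
    for _ in range(spec.debris_count):
        q = int(rng.integers(1, 5))
        placer.place(rng, speck, q, debris_mask, buffer=2.0)
    artifact_mask |= debris_mask

    # render: bright plate with radial-quadratic vignette on dark background
    rows = np.arange(shape[0], dtype=np.float64)[:, None] - geometry.center[0]
    cols = np.arange(shape[1], dtype=np.float64)[None, :] - geometry.center[1]
    dist = np.hypot(rows, cols)
    inside = dist <= geometry.radius
    plate_val = _PLATE_PEAK * (
        1.0 - spec.vignette_strength * (dist / geometry.radius) ** 2
    )
    img = np.full(shape, _BACKGROUND)
    img[inside] = plate_val[inside]
    fg = worm_mask | artifact_mask
    img[fg] = np.maximum(plate_val[fg] - _FOREGROUND_DROP, _FOREGROUND_FLOOR)
    if spec.blur_sigma > 0:
        from scipy import ndimage as ndi

        img = ndi.gaussian_filter(img, sigma=spec.blur_sigma)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)
    if spec.foreground_polarity == "light_on_dark":
        img = 1.0 - img

    counts = np.bincount(regions.labels[worm_mask], minlength=CENTER + 1)
    per_quadrant = tuple(int(counts[q]) for q in (1, 2, 3, 4))
    truth = SyntheticGroundTruth(
        true_geometry=geometry,
        true_area_per_quadrant=per_quadrant,
        true_center_area=int(counts[CENTER]),
        true_debris_pixels=int(artifact_mask.sum()),
        test_pair=spec.test_pair,
        true_ci=compute_ci(
            QuadrantAreas(*per_quadrant, center_px=int(counts[CENTER])),
            spec.test_pair,
        ),
        worm_mask=worm_mask,
        artifact_mask=artifact_mask,
    )
    return GrayscaleImage(pixels=img), truth


MANIFEST_COLUMNS = [
    "image",
    "q1_true_px",
    "q2_true_px",
    "q3_true_px",
    "q4_true_px",
    "center_px",
    "debris_px",
    "true_ci",
    "seed",
]


def generate_batch(
    n: int,
    base_spec: SyntheticPlateSpec,
    seed: int,
    out_dir: str | os.PathLike,
) -> pd.DataFrame:
    """Generate ``n`` plates (seeds ``seed .. seed+n-1``), write PNGs and a
    ground-truth manifest TSV into ``out_dir``; returns the manifest."""
    from .images import write_debug_image

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for i in range(n):
        s = replace(base_spec, seed=seed + i)
        image, truth = generate_synthetic_plate(s)
        name = f"plate_{i:03d}.png"
        write_debug_image(image, os.path.join(out_dir, name))
        q1, q2, q3, q4 = truth.true_area_per_quadrant
        rows.append(
            {
                "image": name,
                "q1_true_px": q1,
                "q2_true_px": q2,
                "q3_true_px": q3,
                "q4_true_px": q4,
                "center_px": truth.true_center_area,
                "debris_px": truth.true_debris_pixels,
                "true_ci": "NA" if truth.true_ci is None else repr(truth.true_ci),
                "seed": s.seed,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    return manifest
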