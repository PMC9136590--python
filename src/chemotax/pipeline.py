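"""End-to-end scoring of plate images: detect -> preprocess -> segment ->
filter -> measure -> CI."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from .errors import ChemotaxError
from .geometry import (
    DetectionConfig,
    PlateGeometry,
    RegionLabelMap,
    build_region_map,
    detect_plate,
)
from .images import GrayscaleImage, load_image, render_overlay, write_debug_image
from .scoring import PlateScore, QuadrantAreas, compute_ci, measure_quadrant_areas
from .segmentation import (
    SegmentationConfig,
    SegmentationResult,
    filter_objects,
    preprocess,
    segment_foreground,
)

logger = logging.getLogger("chemotax")


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one scoring run."""

    test_pair: tuple[int, int] = (1, 3)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    manual_geometry: PlateGeometry | None = None  # bypasses detection


@dataclass(frozen=True)
class StageOutputs:
    """Intermediates of one scored image, for debugging and tests."""

    geometry: PlateGeometry
    regions: RegionLabelMap
    preprocessed: GrayscaleImage
    raw_foreground: object  # binary mask before filtering
    segmentation: SegmentationResult


def score_image(
    image: GrayscaleImage,
    image_id: str,
    config: PipelineConfig | None = None,
    debug_dir: str | os.PathLike | None = None,
) -> tuple[PlateScore, StageOutputs]:
    """Score a single plate image, optionally writing per-stage overlays."""
    cfg = config or PipelineConfig()
    geometry = cfg.manual_geometry or detect_plate(image, cfg.detection)
    regions = build_region_map(geometry, image.shape)
    flattened = preprocess(image, geometry, cfg.segmentation)
    raw_fg = segment_foreground(flattened, geometry, cfg.segmentation)
    seg = filter_objects(raw_fg, geometry, cfg.segmentation)
    areas = measure_quadrant_areas(seg.mask, regions)
    ci = compute_ci(areas, cfg.test_pair)
    score = PlateScore(
        image_id=image_id,
        areas=areas,
        filtered_pixels=seg.filtered_pixels,
        test_pair=tuple(sorted(cfg.test_pair)),
        ci=ci,
    )
    if debug_dir is not None:
        stem = os.path.splitext(os.path.basename(image_id))[0] or "image"
        write_debug_image(flattened, os.path.join(debug_dir, f"{stem}_01_flattened.png"))
        write_debug_image(
            raw_fg.astype(float), os.path.join(debug_dir, f"{stem}_02_foreground.png")
        )
        overlay = render_overlay(
            image,
            geometry=geometry,
            kept_mask=seg.mask,
            filtered_mask=raw_fg & ~seg.mask,
        )
        write_debug_image(overlay, os.path.join(debug_dir, f"{stem}_03_overlay.png"))
    logger.info(
        "%s: center=(%.1f,%.1f) r=%.1f kept=%d filtered=%d ci=%s",
        image_id,
        geometry.center[0],
        geometry.center[1],
        geometry.radius,
        seg.kept_pixels,
        seg.filtered_pixels,
        "NA" if ci is None else f"{ci:.3f}",
    )
    return score, StageOutputs(geometry, regions, flattened, raw_fg, seg)


def score_paths(
    paths,
    config: PipelineConfig | None = None,
    debug_dir: str | os.PathLike | None = None,
) -> tuple[list[PlateScore], int]:
    """Score a batch of image files with per-image failure isolation.

    A failing image yields an all-NA row (zero areas, undefined CI) and is
    logged; processing continues.  Returns the scores in input order and
    the number of failed images.
    """
    cfg = config or PipelineConfig()
    scores: list[PlateScore] = []
    failures = 0
    for path in paths:
        image_id = os.path.basename(os.fspath(path))
        try:
            image = load_image(path)
            score, _ = score_image(image, image_id, cfg, debug_dir)
        except ChemotaxError as exc:
            logger.error("%s: %s", image_id, exc)
            failures += 1
            score = PlateScore(
                image_id=image_id,
                areas=QuadrantAreas(0, 0, 0, 0, 0),
                filtered_pixels=0,
                test_pair=tuple(sorted(cfg.test_pair)),
                ci=None,
            )
        scores.append(score)
    return scores, failures
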