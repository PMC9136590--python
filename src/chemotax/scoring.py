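"""Quadrant area measurement, chemotaxis index, and the results file.

The chemotaxis index (CI) of a plate is

    CI = (A_test - A_control) / (A_test + A_control)

where A_test is the segmented nematode pixel area summed over the diagonal
quadrant pair carrying the test compound and A_control the area over the
other pair.  Pixel area stands proxy for animal counts, which avoids the
errors of counting individual animals in tight clumps.  Animals still in
the center-exclusion zone never left the origin and are excluded from the
denominator (their area is reported separately).  CI ranges from 1
(maximum attraction) to -1 (maximum avoidance); a plate where no animal
left the center has an undefined CI, reported as "NA", never as 0.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import CENTER, DIAGONAL_PAIRS, Q1, Q4, RegionLabelMap

RESULT_COLUMNS = [
    "image",
    "q1_px",
    "q2_px",
    "q3_px",
    "q4_px",
    "center_px",
    "filtered_px",
    "test_pair",
    "ci",
]


@dataclass(frozen=True)
class QuadrantAreas:
    """Kept nematode pixel area per quadrant plus the center-zone area."""

    q1: int
    q2: int
    q3: int
    q4: int
    center_px: int = 0

    def __post_init__(self) -> None:
        for name in ("q1", "q2", "q3", "q4", "center_px"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.q1, self.q2, self.q3, self.q4)

    @property
    def total_quadrant_px(self) -> int:
        return self.q1 + self.q2 + self.q3 + self.q4


@dataclass(frozen=True)
class PlateScore:
    """One output row: per-quadrant areas, filtered pixels and the CI."""

    image_id: str
    areas: QuadrantAreas
    filtered_pixels: int
    test_pair: tuple[int, int] = (1, 3)
    ci: float | None = None

    def __post_init__(self) -> None:
        if self.ci is not None and not -1.0 <= self.ci <= 1.0:
            raise ValidationError(f"ci out of [-1, 1]: {self.ci}")


def _check_pair(test_pair) -> tuple[int, int]:
    pair = tuple(sorted(int(q) for q in test_pair))
    if pair not in DIAGONAL_PAIRS:
        raise ValidationError(
            f"test_pair must be a diagonal pair {DIAGONAL_PAIRS}, got {test_pair}"
        )
    return pair


def measure_quadrant_areas(mask: np.ndarray, regions: RegionLabelMap) -> QuadrantAreas:
    """Sum kept nematode pixels per region.

    Assignment is strictly per pixel: a clump spanning a quadrant boundary
    contributes its pixels to both quadrants, consistent with the
    area-as-proxy principle.
    """
    mask = np.asarray(mask)
    if mask.shape != regions.shape:
        raise ValidationError(
            f"mask shape {mask.shape} != region map shape {regions.shape}"
        )
    counts = np.bincount(regions.labels[mask.astype(bool)], minlength=CENTER + 1)
    return QuadrantAreas(
        q1=int(counts[Q1]),
        q2=int(counts[2]),
        q3=int(counts[3]),
        q4=int(counts[Q4]),
        center_px=int(counts[CENTER]),
    )


def compute_ci(areas: QuadrantAreas, test_pair=(1, 3)) -> float | None:
    """Chemotaxis index from per-quadrant pixel areas.

    Returns ``None`` (undefined) when no pixels lie in any quadrant, i.e.
    no animal left the center region.
    """
    pair = _check_pair(test_pair)
    quads = areas.as_tuple()
    a_test = sum(quads[q - 1] for q in pair)
    a_control = areas.total_quadrant_px - a_test
    denom = a_test + a_control
    if denom == 0:
        return None
    return (a_test - a_control) / denom


def write_results(scores: list[PlateScore], path: str | os.PathLike) -> None:
    """Write the per-image results table as TSV (undefined CI as "NA")."""
    rows = []
    for s in scores:
        rows.append(
            {
                "image": s.image_id,
                "q1_px": s.areas.q1,
                "q2_px": s.areas.q2,
                "q3_px": s.areas.q3,
                "q4_px": s.areas.q4,
                "center_px": s.areas.center_px,
                "filtered_px": s.filtered_pixels,
                "test_pair": f"{s.test_pair[0]},{s.test_pair[1]}",
                "ci": "NA" if s.ci is None else repr(float(s.ci)),
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_results(path: str | os.PathLike) -> list[PlateScore]:
    """Parse a results TSV back into :class:`PlateScore` rows (round-trip)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    scores = []
    for _, row in df.iterrows():
        pair = _check_pair(row["test_pair"].split(","))
        ci = None if row["ci"] == "NA" else float(row["ci"])
        scores.append(
            PlateScore(
                image_id=row["image"],
                areas=QuadrantAreas(
                    q1=int(row["q1_px"]),
                    q2=int(row["q2_px"]),
                    q3=int(row["q3_px"]),
                    q4=int(row["q4_px"]),
                    center_px=int(row["center_px"]),
                ),
                filtered_pixels=int(row["filtered_px"]),
                test_pair=pair,
                ci=ci,
            )
        )
    return scores
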