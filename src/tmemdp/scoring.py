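"""Field-level TMEM counting, top-10 ranking, scoring and risk categories.

The ROI is divided into a disjoint grid of high-power-field tiles; each
TMEM marker is assigned to exactly one tile (the one containing its parent
TA-vessel centroid); tiles are ranked by count and the slide score is the
sum of the top 10. Risk cutoffs 6 (low) and 23 (high) convert the score
into a three-level category.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from . import morphometry, pixel_classifier, stain_features
from .morphometry import (
    MorphometryParams,
    TMEMObjectSet,
    class_union_mask,
    _STRUCT8,
    _boundary,
)
from .slide_io import CalibrationParams, RoiMask, Tile, iter_tiles

__all__ = [
    "ScoringParams",
    "RiskParams",
    "SlideScore",
    "count_per_tile",
    "rank_and_score",
    "alternative_metrics",
    "classify_risk",
    "score_slide",
    "write_report_json",
    "write_report_csv",
    "render_overlay",
]


@dataclass(frozen=True)
class ScoringParams:
    """Field ranking parameters: number of top fields summed and the
    minimum ROI coverage for a tile to be eligible. Ties in the ranking are
    broken by row-major tile index (deterministic)."""

    top_k: int = 10
    min_tile_roi_overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0.0 <= self.min_tile_roi_overlap <= 1.0:
            raise ValueError("min_tile_roi_overlap must lie in [0, 1]")


@dataclass(frozen=True)
class RiskParams:
    """TMEM-score risk cutoffs: low if score <= low_cutoff, high if
    score > high_cutoff, intermediate otherwise."""

    low_cutoff: int = 6
    high_cutoff: int = 23

    def __post_init__(self) -> None:
        if self.low_cutoff >= self.high_cutoff:
            raise ValueError("low_cutoff must be below high_cutoff")


@dataclass
class SlideScore:
    """Per-slide scoring result."""

    score: int
    risk: str
    per_tile_counts: dict[tuple[int, int], int]
    ranked_tiles: list[Tile]  # eligible tiles in rank order
    top_tiles: list[Tile]     # the first top_k of ranked_tiles
    metrics: dict[str, float]  # ta_vessels, ta_macs, interface_um
    params_echo: dict = field(default_factory=dict)

    def tile_count(self, tile: Tile) -> int:
        return self.per_tile_counts.get(tile.index, 0)


def count_per_tile(
    tmem_set: TMEMObjectSet,
    tiles: Sequence[Tile],
    params: ScoringParams | None = None,
) -> tuple[dict[tuple[int, int], int], list[Tile]]:
    """Count TMEM markers per eligible tile.

    A marker belongs to the tile whose half-open extent contains its parent
    TA-vessel centroid, so every marker lands in exactly one tile even when
    the dilated footprint spans several. Tiles with ROI overlap below
    ``min_tile_roi_overlap`` are excluded; markers anchored there are not
    counted.
    """
    params = params or ScoringParams()
    eligible = [t for t in tiles if t.roi_overlap >= params.min_tile_roi_overlap]
    counts = {t.index: 0 for t in eligible}
    lookup = {t.index: t for t in eligible}
    if not eligible:
        return counts, eligible
    t0 = eligible[0]
    for marker in tmem_set.markers:
        cy, cx = marker.parent_centroid
        # tile grid is anchored at the first tile of the full grid; recover
        # indices arithmetically, then verify eligibility
        row = int(np.floor((cy - (t0.y0 - t0.row * t0.height)) / t0.height))
        col = int(np.floor((cx - (t0.x0 - t0.col * t0.width)) / t0.width))
        if (row, col) in counts:
            counts[(row, col)] += 1
    return counts, eligible


def rank_and_score(
    counts: Mapping[tuple[int, int], int],
    tiles: Sequence[Tile],
    params: ScoringParams | None = None,
) -> tuple[int, list[Tile]]:
    """Rank tiles by descending count (row-major index breaks ties) and sum
    the top ``top_k`` counts. Returns (score, ranked tile list)."""
    params = params or ScoringParams()
    ranked = sorted(tiles, key=lambda t: (-counts.get(t.index, 0), t.index))
    top = ranked[: params.top_k]
    score = int(sum(counts.get(t.index, 0) for t in top))
    return score, ranked


def alternative_metrics(
    tmem_set: TMEMObjectSet,
    calibration: CalibrationParams,
) -> dict[str, float]:
    """The three slide-level TMEM quantification metrics.

    ``ta_vessels``: TA-vessel count (the primary score basis);
    ``ta_macs``: TA-macrophage count; ``interface_um``: total boundary
    length shared between TA macrophages and TA vessels, in micrometers
    (TA-mac boundary pixels 8-adjacent to TA-vessel pixels, times the pixel
    pitch).
    """
    n_vessels = len(tmem_set.ta_vessels)
    n_macs = len(tmem_set.ta_macrophages)
    if n_vessels == 0 or n_macs == 0:
        return {"ta_vessels": float(n_vessels), "ta_macs": float(n_macs), "interface_um": 0.0}
    shape = tmem_set.ta_vessels[0].image_shape
    vessel_mask = class_union_mask(tmem_set.ta_vessels, shape)
    near_vessel = ndimage.binary_dilation(vessel_mask, structure=_STRUCT8)
    interface_px = 0
    for m in tmem_set.ta_macrophages:
        h, w = m.image_shape
        r0 = max(m.slices[0].start - 1, 0)
        r1 = min(m.slices[0].stop + 1, h)
        c0 = max(m.slices[1].start - 1, 0)
        c1 = min(m.slices[1].stop + 1, w)
        patch = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        pr = m.slices[0].start - r0
        pc = m.slices[1].start - c0
        patch[pr : pr + m.mask.shape[0], pc : pc + m.mask.shape[1]] = m.mask
        boundary = _boundary(patch)
        interface_px += int((boundary & near_vessel[r0:r1, c0:c1]).sum())
    return {
        "ta_vessels": float(n_vessels),
        "ta_macs": float(n_macs),
        "interface_um": interface_px * calibration.microns_per_pixel,
    }


def classify_risk(score: int, params: RiskParams | None = None) -> str:
    """Map a TMEM score to 'low', 'intermediate' or 'high'."""
    if score < 0:
        raise ValueError("score must be >= 0")
    params = params or RiskParams()
    if score <= params.low_cutoff:
        return "low"
    if score > params.high_cutoff:
        return "high"
    return "intermediate"


def score_slide(
    image: np.ndarray,
    roi: RoiMask,
    model: pixel_classifier.ClassifierModel,
    calibration: CalibrationParams,
    stain_matrix: stain_features.StainMatrix | None = None,
    morph_params: MorphometryParams | None = None,
    scoring_params: ScoringParams | None = None,
    risk_params: RiskParams | None = None,
    median_radius: int = 1,
) -> SlideScore:
    """End-to-end TMEM scoring of one slide image.

    Runs stain unmixing, pixel classification, object formation/filtering,
    the reclassification cascade, marker creation, tiling, counting and
    ranking. Fully deterministic: identical inputs give identical scores.
    """
    if roi.is_empty:
        raise ValueError("ROI is empty; scoring requires a nonempty region")
    if roi.shape != image.shape[:2]:
        raise ValueError("ROI grid does not match image grid")
    morph_params = morph_params or MorphometryParams()
    scoring_params = scoring_params or ScoringParams()
    risk_params = risk_params or RiskParams()

    stack = stain_features.extract_features(image, stain_matrix, median_radius)
    label_map = pixel_classifier.classify(stack, model)
    # restrict analysis to the ROI: outside pixels become stroma
    label_map = np.where(roi.mask, label_map, np.uint8(pixel_classifier.LabelScheme.STROMA))
    objects = morphometry.form_objects(label_map, calibration, morph_params)
    objects = morphometry.filter_objects(objects, morph_params)
    tmem_set = morphometry.reclassify_cascade(objects, morph_params)
    tmem_set = morphometry.make_tmem_objects(tmem_set, calibration, morph_params)

    tiles = list(iter_tiles(image.shape[:2], roi, calibration))
    counts, eligible = count_per_tile(tmem_set, tiles, scoring_params)
    score, ranked = rank_and_score(counts, eligible, scoring_params)
    metrics = alternative_metrics(tmem_set, calibration)
    return SlideScore(
        score=score,
        risk=classify_risk(score, risk_params),
        per_tile_counts=counts,
        ranked_tiles=ranked,
        top_tiles=ranked[: scoring_params.top_k],
        metrics=metrics,
        params_echo={
            "calibration": vars(calibration).copy() if hasattr(calibration, "__dict__") else {
                "microns_per_pixel": calibration.microns_per_pixel,
                "tile_width_um": calibration.tile_width_um,
                "tile_height_um": calibration.tile_height_um,
            },
            "morphometry": {k: getattr(morph_params, k) for k in morph_params.__dataclass_fields__},
            "scoring": {k: getattr(scoring_params, k) for k in scoring_params.__dataclass_fields__},
            "risk": {k: getattr(risk_params, k) for k in risk_params.__dataclass_fields__},
        },
    )


def _tile_rows(result: SlideScore) -> list[dict]:
    rank_of = {t.index: r for r, t in enumerate(result.ranked_tiles, start=1)}
    rows = []
    for t in result.ranked_tiles:
        rows.append(
            {
                "row": t.row,
                "col": t.col,
                "x_px": t.x0,
                "y_px": t.y0,
                "count": result.per_tile_counts.get(t.index, 0),
                "rank": rank_of[t.index],
            }
        )
    return rows


def write_report_json(result: SlideScore, path: str | Path) -> None:
    payload = {
        "score": result.score,
        "risk": result.risk,
        "metrics": result.metrics,
        "tiles": _tile_rows(result),
        "params_echo": result.params_echo,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_report_csv(result: SlideScore, path: str | Path) -> None:
    rows = _tile_rows(result)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["row", "col", "x_px", "y_px", "count", "rank"])
        writer.writeheader()
        writer.writerows(rows)


def render_overlay(
    image: np.ndarray,
    result: SlideScore,
    tmem_set: TMEMObjectSet | None = None,
) -> np.ndarray:
    """Draw the top-ranked tile rectangles (yellow) and, when a TMEM object
    set is given, marker outlines (dark blue) on a copy of the image."""
    out = np.asarray(image).copy()
    yellow = np.array([255, 220, 0], dtype=np.uint8)
    blue = np.array([20, 20, 160], dtype=np.uint8)
    h, w = out.shape[:2]
    for t in result.top_tiles:
        y1 = min(t.y0 + t.height, h) - 1
        x1 = min(t.x0 + t.width, w) - 1
        out[t.y0 : y1 + 1, [t.x0, x1]] = yellow
        out[[t.y0, y1], t.x0 : x1 + 1] = yellow
    if tmem_set is not None:
        for marker in tmem_set.markers:
            edge = marker.mask & ~ndimage.binary_erosion(marker.mask, structure=_STRUCT8)
            sub = out[marker.slices]
            sub[edge] = blue
    return out
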