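"""Synthetic triple-IHC-like slides with planted TMEM triads.

Real cohort slides are not redistributable, so validation runs on rendered
stand-ins: a light-green stroma background, two-tone pink/red tumor nests,
blue vessels and brown macrophages, drawn as anti-aliasing-free filled
shapes on the pixel grid so every contact fraction is exactly computable.
Each planted triad is a vessel wrapped by an L-shaped macrophage inside a
tumor nest, sized so that every cascade gate is exceeded with at least a
2x margin (verified against the discrete contact definition at build
time). Distractors each violate exactly one gate. RGB noise is added after
geometry and never moves class boundaries.

The default rendering scale is 1.0 um/px: every area threshold of the
cascade (5-800 um^2) is an exact pixel count at this scale and the default
900 x 800 px slide is an exact 3 x 2 grid of 300 x 400 um high-power
fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

from . import morphometry
from .morphometry import DerivedLabel, MorphometryParams, ObjectClass
from .pixel_classifier import LabelScheme
from .slide_io import CalibrationParams
from .scoring import ScoringParams

__all__ = [
    "SlideSpec",
    "GroundTruth",
    "PALETTE",
    "DISTRACTOR_KINDS",
    "generate_slide",
    "generate_training_set",
    "expected_score",
]

# render palette, one RGB color per pixel class (config-overridable)
PALETTE: dict[int, tuple[int, int, int]] = {
    int(LabelScheme.VESSEL): (70, 90, 200),
    int(LabelScheme.MACROPHAGE): (120, 80, 30),
    int(LabelScheme.TUMOR_LIGHT): (230, 150, 180),
    int(LabelScheme.TUMOR_DARK): (200, 60, 90),
    int(LabelScheme.STROMA): (200, 230, 200),
}

DISTRACTOR_KINDS = (
    "isolated_macrophage",
    "vessel_no_macrophage",
    "no_tumor_contact",
    "aggregate",
    "fragment",
)


@dataclass(frozen=True)
class SlideSpec:
    """Layout specification of one synthetic slide.

    Planted structures sit on a jittered grid whose pitch exceeds twice the
    marker dilation radius plus smoothing, so markers and contacts of
    different plants can never interact.
    """

    width_px: int = 900
    height_px: int = 800
    microns_per_pixel: float = 1.0
    n_tmem_triads: int = 7
    n_distractors: dict[str, int] = field(
        default_factory=lambda: {k: 1 for k in DISTRACTOR_KINDS}
    )
    palette: dict[int, tuple[int, int, int]] = field(default_factory=lambda: dict(PALETTE))
    noise_sigma: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tmem_triads < 0:
            raise ValueError("n_tmem_triads must be >= 0")
        for kind, n in self.n_distractors.items():
            if kind not in DISTRACTOR_KINDS:
                raise ValueError(f"unknown distractor kind: {kind}")
            if n < 0:
                raise ValueError("distractor counts must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def calibration(self) -> CalibrationParams:
        return CalibrationParams(microns_per_pixel=self.microns_per_pixel)


@dataclass
class PlantedTriad:
    vessel_centroid: tuple[float, float]  # (row, col) px
    macrophage_area_um2: float
    contacts: dict[str, float]  # constructed contact fractions


@dataclass
class GroundTruth:
    """What was planted, and what a perfect analysis should recover."""

    triads: list[PlantedTriad]
    distractors: list[tuple[str, tuple[int, int]]]  # (kind, (row, col) anchor)
    expected_count: int
    label_mask: np.ndarray


# ---------------------------------------------------------------------------
# canonical geometry (all coordinates in pixels at 1 um/px; other scales
# multiply linear dimensions by 1/mpp)

def _stamp_triad(mask: np.ndarray, r: int, c: int, s: int = 1) -> tuple[float, float]:
    """Stamp one canonical triad with its top-left block corner at (r, c).

    Layout (s = linear scale factor): a 10x10 vessel wrapped on its right
    and bottom by an L-shaped macrophage of arm thickness 3, with tumor
    filling the rest of a nest that extends 6 px beyond the block. Returns
    the vessel centroid (row, col).
    """
    m = 6 * s  # nest margin
    bh, bw = 13 * s, 16 * s  # structure block
    # two-tone tumor nest (left half dark, right half light)
    nest = (slice(r - m, r + bh + m), slice(c - m, c + bw + m))
    mid = c + (bw // 2)
    mask[nest[0], slice(c - m, mid)] = LabelScheme.TUMOR_DARK
    mask[nest[0], slice(mid, c + bw + m)] = LabelScheme.TUMOR_LIGHT
    # vessel 10x10 at block cols 3..12
    mask[r : r + 10 * s, c + 3 * s : c + 13 * s] = LabelScheme.VESSEL
    # macrophage L: right arm and bottom arm, thickness 3
    mask[r : r + 13 * s, c + 13 * s : c + 16 * s] = LabelScheme.MACROPHAGE
    mask[r + 10 * s : r + 13 * s, c : c + 16 * s] = LabelScheme.MACROPHAGE
    return (r + (10 * s) / 2.0 - 0.5, c + 3 * s + (10 * s) / 2.0 - 0.5)


def _stamp_distractor(mask: np.ndarray, kind: str, r: int, c: int, s: int = 1) -> None:
    """Stamp a structure that fails exactly one cascade stage."""
    m = 6 * s
    if kind == "isolated_macrophage":
        # macrophage in tumor, no vessel anywhere near -> never a complex
        mask[r - m : r + 9 * s + m, c - m : c + 9 * s + m] = LabelScheme.TUMOR_LIGHT
        mask[r : r + 9 * s, c : c + 9 * s] = LabelScheme.MACROPHAGE
    elif kind == "vessel_no_macrophage":
        # vessel in tumor with zero macrophage contact -> fails step (a)
        mask[r - m : r + 10 * s + m, c - m : c + 10 * s + m] = LabelScheme.TUMOR_DARK
        mask[r : r + 10 * s, c : c + 10 * s] = LabelScheme.VESSEL
    elif kind == "no_tumor_contact":
        # full vessel+macrophage pair but embedded in stroma -> fails the
        # tumor-contact gates of steps (c)/(d)
        mask[r : r + 10 * s, c + 3 * s : c + 13 * s] = LabelScheme.VESSEL
        mask[r : r + 13 * s, c + 13 * s : c + 16 * s] = LabelScheme.MACROPHAGE
        mask[r + 10 * s : r + 13 * s, c : c + 16 * s] = LabelScheme.MACROPHAGE
    elif kind == "aggregate":
        # oversized vessel (> 800 um^2) with macrophage and tumor around:
        # removed by the size filter before the cascade
        side = 30 * s
        mask[r - m : r + side + 3 * s + m, c - m : c + side + 3 * s + m] = (
            LabelScheme.TUMOR_LIGHT
        )
        mask[r : r + side, c : c + side] = LabelScheme.VESSEL
        mask[r : r + side, c + side : c + side + 3 * s] = LabelScheme.MACROPHAGE
    elif kind == "fragment":
        # sub-5 um^2 vessel speck beside a macrophage: speck is filtered out
        mask[r - m : r + 9 * s + m, c - m : c + 9 * s + m] = LabelScheme.TUMOR_DARK
        mask[r : r + 2, c : c + 2] = LabelScheme.VESSEL  # 4 px = 4 um^2 at s=1
        mask[r : r + 9 * s, c + 3 * s : c + 9 * s] = LabelScheme.MACROPHAGE
    else:
        raise ValueError(f"unknown distractor kind: {kind}")


_CASCADE_GATES = (
    ("vessel_mac", "vessel macrophage contact"),
    ("mac_vessel", "macrophage vessel contact"),
    ("mac_tumor", "macrophage tumor contact"),
    ("vessel_tumor", "vessel tumor contact"),
    ("vessel_ta_mac", "vessel TA-macrophage contact"),
)


@lru_cache(maxsize=8)
def _verified_triad_contacts(mpp: float, smoothing_radius_um: float) -> dict[str, float]:
    """Build one canonical triad in isolation and measure its contact
    fractions with the package's own discrete adjacency definition (after
    the same smoothing the pipeline applies), asserting a >= 2x margin over
    every cascade gate. Cached: the geometry is deterministic."""
    params = MorphometryParams(smoothing_radius_um=smoothing_radius_um)
    calib = CalibrationParams(microns_per_pixel=mpp)
    s = max(int(round(1.0 / mpp)), 1)
    pad = 20 * s
    mask = np.full((13 * s + 2 * pad, 16 * s + 2 * pad), int(LabelScheme.STROMA), np.uint8)
    _stamp_triad(mask, pad, pad, s)
    objects = morphometry.form_objects(mask, calib, params)
    objects = morphometry.filter_objects(objects, params)
    tmem = morphometry.reclassify_cascade(objects, params)
    if len(tmem.ta_vessels) != 1 or len(tmem.ta_macrophages) != 1:
        raise AssertionError("canonical triad did not survive the cascade")
    v = tmem.ta_vessels[0]
    mac = tmem.ta_macrophages[0]
    contacts = {
        "vessel_mac": v.contacts["macrophage"],
        "mac_vessel": mac.contacts["vessel"],
        "mac_tumor": mac.contacts["tumor"],
        "vessel_tumor": v.contacts["tumor"],
        "vessel_ta_mac": v.contacts["ta_macrophage"],
    }
    mac_large = mac.area_um2 >= params.large_mac_threshold_um2
    gates = {
        "vessel_mac": params.vessel_mac_contact_min,
        "mac_vessel": params.large_mac_vessel_contact_min
        if mac_large
        else params.small_mac_vessel_contact_min,
        "mac_tumor": params.large_mac_tumor_contact_min
        if mac_large
        else params.small_mac_tumor_contact_min,
        "vessel_tumor": params.ta_vessel_tumor_contact_min,
        "vessel_ta_mac": params.ta_vessel_mac_contact_min,
    }
    for key, gate in gates.items():
        if contacts[key] < 2.0 * gate:
            raise AssertionError(
                f"triad {key} contact {contacts[key]:.3f} below 2x gate {gate}"
            )
    contacts["macrophage_area_um2"] = mac.area_um2
    return contacts


def _slot_grid(spec: SlideSpec, s: int) -> list[tuple[int, int]]:
    """Anchor positions whose pitch honors the separation invariant."""
    params = MorphometryParams()
    pitch = int(
        2 * (params.tmem_dilation_um + params.smoothing_radius_um) / spec.microns_per_pixel
    ) + 6 * s
    margin = 25 * s  # nest half-extent plus slack from the image edge
    rows = list(range(margin, spec.height_px - margin - 13 * s, pitch))
    cols = list(range(margin, spec.width_px - margin - 16 * s, pitch))
    return [(r, c) for r in rows for c in cols]


def generate_slide(spec: SlideSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render one synthetic slide.

    Returns (RGB image, per-pixel label mask with :class:`LabelScheme`
    codes, ground truth). Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    s = max(int(round(1.0 / spec.microns_per_pixel)), 1)
    triad_contacts = _verified_triad_contacts(
        spec.microns_per_pixel, MorphometryParams().smoothing_radius_um
    )
    mask = np.full(
        (spec.height_px, spec.width_px), int(LabelScheme.STROMA), dtype=np.uint8
    )
    slots = _slot_grid(spec, s)
    n_needed = spec.n_tmem_triads + sum(spec.n_distractors.values())
    if n_needed > len(slots):
        raise ValueError(
            f"spec too dense: {n_needed} structures but only {len(slots)} "
            "positions honor the separation invariant"
        )
    order = rng.permutation(len(slots))
    cursor = 0
    triads: list[PlantedTriad] = []
    for _ in range(spec.n_tmem_triads):
        r, c = slots[order[cursor]]
        cursor += 1
        centroid = _stamp_triad(mask, r, c, s)
        triads.append(
            PlantedTriad(
                vessel_centroid=centroid,
                macrophage_area_um2=triad_contacts["macrophage_area_um2"],
                contacts={k: v for k, v in triad_contacts.items() if k != "macrophage_area_um2"},
            )
        )
    distractors: list[tuple[str, tuple[int, int]]] = []
    for kind in DISTRACTOR_KINDS:
        for _ in range(spec.n_distractors.get(kind, 0)):
            r, c = slots[order[cursor]]
            cursor += 1
            _stamp_distractor(mask, kind, r, c, s)
            distractors.append((kind, (r, c)))

    image = render_image(mask, spec.palette, spec.noise_sigma, rng)
    truth = GroundTruth(
        triads=triads,
        distractors=distractors,
        expected_count=len(triads),
        label_mask=mask,
    )
    return image, mask, truth


def render_image(
    label_mask: np.ndarray,
    palette: dict[int, tuple[int, int, int]] | None = None,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Map a label mask to RGB through the palette and add clipped Gaussian
    noise (applied after geometry: class boundaries never move)."""
    palette = palette or PALETTE
    lut = np.zeros((256, 3), dtype=np.float32)
    for code, color in palette.items():
        lut[code] = color
    image = lut[label_mask]
    if noise_sigma > 0:
        rng = rng or np.random.default_rng(0)
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    return np.clip(np.round(image), 0, 255).astype(np.uint8)


def generate_training_set(
    spec: SlideSpec, n_images: int = 6
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Annotated fields of view for classifier training.

    Each image is a small field containing all five classes (a triad plus
    isolated structures), paired with its exact label mask. Layouts differ
    by image; palette and noise follow ``spec``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    s = max(int(round(1.0 / spec.microns_per_pixel)), 1)
    side = 220 * s
    out = []
    for i in range(n_images):
        rng = np.random.default_rng(spec.seed + 7919 * (i + 1))
        mask = np.full((side, side), int(LabelScheme.STROMA), dtype=np.uint8)
        jr, jc = rng.integers(0, 10 * s, size=2)
        _stamp_triad(mask, 30 * s + jr, 30 * s + jc, s)
        _stamp_distractor(mask, "isolated_macrophage", 120 * s, 30 * s + jc, s)
        _stamp_distractor(mask, "vessel_no_macrophage", 30 * s + jr, 120 * s, s)
        # a plain two-tone tumor nest for extra tumor pixels
        mask[120 * s : 160 * s, 120 * s : 140 * s] = LabelScheme.TUMOR_DARK
        mask[120 * s : 160 * s, 140 * s : 160 * s] = LabelScheme.TUMOR_LIGHT
        image = render_image(mask, spec.palette, spec.noise_sigma, rng)
        out.append((image, mask))
    return out


def expected_score(
    truth: GroundTruth,
    calibration: CalibrationParams,
    scoring_params: ScoringParams | None = None,
) -> int:
    """Score implied by the planted layout alone (no image analysis):
    assign each planted vessel centroid to its HPF tile and sum the top-k
    tile counts. The oracle for plant-and-recover checks."""
    scoring_params = scoring_params or ScoringParams()
    tile_h = calibration.um_to_px(calibration.tile_height_um)
    tile_w = calibration.um_to_px(calibration.tile_width_um)
    counts: dict[tuple[int, int], int] = {}
    for triad in truth.triads:
        cy, cx = triad.vessel_centroid
        key = (int(cy // tile_h), int(cx // tile_w))
        counts[key] = counts.get(key, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return int(sum(v for _, v in ranked[: scoring_params.top_k]))
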