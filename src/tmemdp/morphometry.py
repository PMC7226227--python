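"""Object morphometry and the TMEM reclassification cascade.

From the per-pixel label map this module forms smoothed connected-component
objects, removes implausibly small fragments and oversized aggregates, and
then walks the contact cascade that defines a TMEM doorway:

(a) vessels with >= 2% of their perimeter touching macrophages become
    vessel-macrophage complexes;
(b) macrophages touching such a complex become macrophage-vessel complexes;
(c) those complexes are promoted to TMEM-associated (TA) macrophages if
    their tumor and vessel contacts exceed size-dependent gates
    (>= 40 um^2: 8% tumor and 20% vessel; < 40 um^2: 10% and 10%);
(d) vessel-macrophage complexes with >= 20% tumor contact and >= 20%
    TA-macrophage contact become TA vessels;
(e) everything that is not TA is discarded.

Each TA vessel is finally dilated by a 50 um disk to produce one TMEM
marker object, the unit that is counted per high-power field.

All contact fractions use a discrete perimeter definition: a boundary pixel
is an object pixel with at least one non-object 8-neighbor (pixels on the
image edge count), and the contact fraction is the share of boundary pixels
8-adjacent to the neighbor class. The ratio is unit free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .pixel_classifier import LabelScheme
from .slide_io import CalibrationParams

__all__ = [
    "ObjectClass",
    "DerivedLabel",
    "MorphometryParams",
    "TissueObject",
    "TmemMarker",
    "TMEMObjectSet",
    "form_objects",
    "filter_objects",
    "contact_fraction",
    "reclassify_cascade",
    "make_tmem_objects",
    "class_union_mask",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


class ObjectClass(IntEnum):
    """Merged object classes (the two tumor tones collapse into TUMOR)."""

    STROMA = 0
    TUMOR = 1
    MACROPHAGE = 2
    VESSEL = 3


class DerivedLabel(IntEnum):
    """Labels assigned during the reclassification cascade."""

    VESSEL_MAC_COMPLEX = 10
    MAC_VESSEL_COMPLEX = 11
    TA_MACROPHAGE_LARGE = 12
    TA_MACROPHAGE_SMALL = 13
    TA_VESSEL = 14


# painting order for overlap resolution after per-class closing:
# rarest structures win (VESSEL over MACROPHAGE over TUMOR over STROMA)
_PAINT_ORDER = (
    ObjectClass.STROMA,
    ObjectClass.TUMOR,
    ObjectClass.MACROPHAGE,
    ObjectClass.VESSEL,
)


@dataclass(frozen=True)
class MorphometryParams:
    """Morphometric thresholds, in physical units.

    Area filters use strict inequalities exactly as printed (an 800 um^2
    vessel is kept, a 5.0 um^2 macrophage is kept); contact and area gates
    in the cascade are inclusive ("at least").
    """

    max_vessel_or_mac_aggregate_um2: float = 800.0
    min_tumor_fragment_um2: float = 10.0
    min_stroma_um2: float = 400.0
    min_macrophage_um2: float = 5.0
    min_vessel_um2: float = 5.0
    vessel_mac_contact_min: float = 0.02
    large_mac_threshold_um2: float = 40.0
    large_mac_tumor_contact_min: float = 0.08
    large_mac_vessel_contact_min: float = 0.20
    small_mac_tumor_contact_min: float = 0.10
    small_mac_vessel_contact_min: float = 0.10
    ta_vessel_tumor_contact_min: float = 0.20
    ta_vessel_mac_contact_min: float = 0.20
    tmem_dilation_um: float = 50.0
    smoothing_radius_um: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "max_vessel_or_mac_aggregate_um2",
            "min_tumor_fragment_um2",
            "min_stroma_um2",
            "min_macrophage_um2",
            "min_vessel_um2",
            "large_mac_threshold_um2",
            "tmem_dilation_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "vessel_mac_contact_min",
            "large_mac_tumor_contact_min",
            "large_mac_vessel_contact_min",
            "small_mac_tumor_contact_min",
            "small_mac_vessel_contact_min",
            "ta_vessel_tumor_contact_min",
            "ta_vessel_mac_contact_min",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.smoothing_radius_um < 0:
            raise ValueError("smoothing_radius_um must be >= 0")


@dataclass
class TissueObject:
    """One connected component with its morphometric measurements.

    ``slices`` is the bounding box in global image coordinates and ``mask``
    the boolean patch inside it. ``contacts`` caches perimeter-contact
    fractions keyed by neighbor-class name.
    """

    id: int
    cls: ObjectClass
    slices: tuple[slice, slice]
    mask: np.ndarray
    area_um2: float
    boundary_px: int
    perimeter_um: float
    image_shape: tuple[int, int]
    label: DerivedLabel | None = None
    contacts: dict[str, float] = field(default_factory=dict)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def centroid(self) -> tuple[float, float]:
        """(row, col) centroid of the pixel set, in global coordinates."""
        rr, cc = np.nonzero(self.mask)
        return (
            float(rr.mean()) + self.slices[0].start,
            float(cc.mean()) + self.slices[1].start,
        )

    def full_mask(self) -> np.ndarray:
        out = np.zeros(self.image_shape, dtype=bool)
        out[self.slices] = self.mask
        return out


@dataclass
class TmemMarker:
    """A TMEM marker: the 50 um dilation of one TA vessel."""

    parent_id: int
    parent_centroid: tuple[float, float]  # (row, col) of the TA vessel
    slices: tuple[slice, slice]
    mask: np.ndarray
    area_um2: float


@dataclass
class TMEMObjectSet:
    """Final cascade output: TA vessels, TA macrophages and markers."""

    ta_vessels: list[TissueObject] = field(default_factory=list)
    ta_macrophages_large: list[TissueObject] = field(default_factory=list)
    ta_macrophages_small: list[TissueObject] = field(default_factory=list)
    markers: list[TmemMarker] = field(default_factory=list)

    @property
    def ta_macrophages(self) -> list[TissueObject]:
        return self.ta_macrophages_large + self.ta_macrophages_small

    @property
    def n_tmem(self) -> int:
        return len(self.markers)


def _closing(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Morphological closing with a disk, exact on a zero background."""
    if radius_px <= 0 or not mask.any():
        return mask
    yy, xx = np.mgrid[-radius_px : radius_px + 1, -radius_px : radius_px + 1]
    disk = (yy * yy + xx * xx) <= radius_px * radius_px
    padded = np.pad(mask, radius_px)
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(padded, structure=disk), structure=disk
    )
    return closed[radius_px:-radius_px, radius_px:-radius_px]


def _boundary(mask_patch: np.ndarray) -> np.ndarray:
    """Boundary pixels of a patch; outside the patch counts as background,
    so the caller must pass patches clipped at the true image edge."""
    eroded = ndimage.binary_erosion(mask_patch, structure=_STRUCT8, border_value=0)
    return mask_patch & ~eroded


def _measure(
    obj_id: int,
    cls: ObjectClass,
    slices: tuple[slice, slice],
    mask: np.ndarray,
    calibration: CalibrationParams,
    image_shape: tuple[int, int],
) -> TissueObject:
    boundary = _boundary(mask)
    n_boundary = int(boundary.sum())
    return TissueObject(
        id=obj_id,
        cls=cls,
        slices=slices,
        mask=mask,
        area_um2=calibration.area_px_to_um2(int(mask.sum())),
        boundary_px=n_boundary,
        perimeter_um=n_boundary * calibration.microns_per_pixel,
        image_shape=image_shape,
    )


def form_objects(
    label_map: np.ndarray,
    calibration: CalibrationParams,
    params: MorphometryParams | None = None,
) -> dict[ObjectClass, list[TissueObject]]:
    """Merge the tumor tones, smooth class boundaries, and label objects.

    The two tumor classes are merged, each merged-class mask is closed with
    a disk of ``smoothing_radius_um`` (dilate then erode), overlaps created
    by closing are resolved by priority VESSEL > MACROPHAGE > TUMOR >
    STROMA, and 8-connected components become :class:`TissueObject`s.
    """
    params = params or MorphometryParams()
    label_map = np.asarray(label_map)
    h, w = label_map.shape
    radius_px = calibration.um_to_px(params.smoothing_radius_um)
    raw_masks = {
        ObjectClass.STROMA: label_map == LabelScheme.STROMA,
        ObjectClass.TUMOR: (label_map == LabelScheme.TUMOR_DARK)
        | (label_map == LabelScheme.TUMOR_LIGHT),
        ObjectClass.MACROPHAGE: label_map == LabelScheme.MACROPHAGE,
        ObjectClass.VESSEL: label_map == LabelScheme.VESSEL,
    }
    merged = np.full((h, w), int(ObjectClass.STROMA), dtype=np.uint8)
    for cls in _PAINT_ORDER:
        closed = _closing(raw_masks[cls], radius_px)
        merged[closed] = int(cls)

    objects: dict[ObjectClass, list[TissueObject]] = {c: [] for c in ObjectClass}
    next_id = 1
    for cls in ObjectClass:
        labeled, n = ndimage.label(merged == int(cls), structure=_STRUCT8)
        for idx, sl in enumerate(ndimage.find_objects(labeled), start=1):
            patch = labeled[sl] == idx
            objects[cls].append(
                _measure(next_id, cls, (sl[0], sl[1]), patch, calibration, (h, w))
            )
            next_id += 1
    return objects


def filter_objects(
    objects: Mapping[ObjectClass, Sequence[TissueObject]],
    params: MorphometryParams | None = None,
) -> dict[ObjectClass, list[TissueObject]]:
    """Drop oversized vessel/macrophage aggregates and small fragments.

    Removes VESSEL and MACROPHAGE objects with area > 800 um^2, TUMOR
    < 10 um^2, STROMA < 400 um^2, MACROPHAGE < 5 um^2 and VESSEL < 5 um^2
    (strict inequalities; objects exactly at a boundary are kept).
    """
    params = params or MorphometryParams()
    out: dict[ObjectClass, list[TissueObject]] = {c: [] for c in ObjectClass}
    for cls, objs in objects.items():
        for obj in objs:
            a = obj.area_um2
            if cls in (ObjectClass.VESSEL, ObjectClass.MACROPHAGE):
                if a > params.max_vessel_or_mac_aggregate_um2:
                    continue
                min_area = (
                    params.min_vessel_um2
                    if cls is ObjectClass.VESSEL
                    else params.min_macrophage_um2
                )
                if a < min_area:
                    continue
            elif cls is ObjectClass.TUMOR and a < params.min_tumor_fragment_um2:
                continue
            elif cls is ObjectClass.STROMA and a < params.min_stroma_um2:
                continue
            out[ObjectClass(cls)].append(obj)
    return out


def class_union_mask(
    objects: Iterable[TissueObject], image_shape: tuple[int, int]
) -> np.ndarray:
    """Union pixel mask of a collection of objects on the full image grid."""
    out = np.zeros(image_shape, dtype=bool)
    for obj in objects:
        out[obj.slices] |= obj.mask
    return out


def contact_fraction(obj: TissueObject, neighbor_mask: np.ndarray) -> float:
    """Fraction of the object's boundary pixels 8-adjacent to the neighbor.

    ``neighbor_mask`` is a full-image boolean mask of the neighbor class.
    """
    if obj.n_pixels == 0:
        raise ValueError("empty object")
    h, w = obj.image_shape
    r0 = max(obj.slices[0].start - 1, 0)
    r1 = min(obj.slices[0].stop + 1, h)
    c0 = max(obj.slices[1].start - 1, 0)
    c1 = min(obj.slices[1].stop + 1, w)
    patch = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    pr = obj.slices[0].start - r0
    pc = obj.slices[1].start - c0
    patch[pr : pr + obj.mask.shape[0], pc : pc + obj.mask.shape[1]] = obj.mask
    boundary = _boundary(patch)
    n_boundary = int(boundary.sum())
    if n_boundary == 0:  # single interior pixel fully enclosed cannot happen
        return 0.0
    neigh = np.asarray(neighbor_mask, dtype=bool)[r0:r1, c0:c1] & ~patch
    if not neigh.any():
        return 0.0
    near = ndimage.binary_dilation(neigh, structure=_STRUCT8)
    return float((boundary & near).sum()) / n_boundary


def reclassify_cascade(
    objects: Mapping[ObjectClass, Sequence[TissueObject]],
    params: MorphometryParams | None = None,
) -> TMEMObjectSet:
    """Run cascade steps (a)-(e) on filtered objects.

    Vessel contact in step (c) and tumor contact throughout are measured
    against the union masks of all post-filter vessels / tumor; the TA
    macrophage mask for step (d) is recomputed after step (c).
    """
    params = params or MorphometryParams()
    vessels = list(objects.get(ObjectClass.VESSEL, ()))
    macs = list(objects.get(ObjectClass.MACROPHAGE, ()))
    result = TMEMObjectSet()
    if not vessels or not macs:
        return result
    shape = vessels[0].image_shape
    vessel_mask = class_union_mask(vessels, shape)
    mac_mask = class_union_mask(macs, shape)
    tumor_mask = class_union_mask(objects.get(ObjectClass.TUMOR, ()), shape)

    # (a) vessel-macrophage complexes
    complexes: list[TissueObject] = []
    for v in vessels:
        frac = contact_fraction(v, mac_mask)
        v.contacts["macrophage"] = frac
        if frac >= params.vessel_mac_contact_min:
            v.label = DerivedLabel.VESSEL_MAC_COMPLEX
            complexes.append(v)
    if not complexes:
        return result
    complex_mask = class_union_mask(complexes, shape)

    # (b) macrophage-vessel complexes: any contact with a complex
    mv_complexes: list[TissueObject] = []
    for m in macs:
        frac = contact_fraction(m, complex_mask)
        m.contacts["vessel_mac_complex"] = frac
        if frac > 0.0:
            m.label = DerivedLabel.MAC_VESSEL_COMPLEX
            mv_complexes.append(m)

    # (c) TA macrophages, size-dependent gates
    for m in mv_complexes:
        tumor_c = contact_fraction(m, tumor_mask)
        vessel_c = contact_fraction(m, vessel_mask)
        m.contacts["tumor"] = tumor_c
        m.contacts["vessel"] = vessel_c
        if m.area_um2 >= params.large_mac_threshold_um2:
            if (
                tumor_c >= params.large_mac_tumor_contact_min
                and vessel_c >= params.large_mac_vessel_contact_min
            ):
                m.label = DerivedLabel.TA_MACROPHAGE_LARGE
                result.ta_macrophages_large.append(m)
        else:
            if (
                tumor_c >= params.small_mac_tumor_contact_min
                and vessel_c >= params.small_mac_vessel_contact_min
            ):
                m.label = DerivedLabel.TA_MACROPHAGE_SMALL
                result.ta_macrophages_small.append(m)
    if not result.ta_macrophages:
        return result
    ta_mac_mask = class_union_mask(result.ta_macrophages, shape)

    # (d) TA vessels
    for v in complexes:
        tumor_c = contact_fraction(v, tumor_mask)
        ta_mac_c = contact_fraction(v, ta_mac_mask)
        v.contacts["tumor"] = tumor_c
        v.contacts["ta_macrophage"] = ta_mac_c
        if (
            tumor_c >= params.ta_vessel_tumor_contact_min
            and ta_mac_c >= params.ta_vessel_mac_contact_min
        ):
            v.label = DerivedLabel.TA_VESSEL
            result.ta_vessels.append(v)
    # (e) everything else is already excluded from the result
    return result


def make_tmem_objects(
    tmem_set: TMEMObjectSet,
    calibration: CalibrationParams,
    params: MorphometryParams | None = None,
) -> TMEMObjectSet:
    """Dilate each TA vessel by a 50 um disk into one TMEM marker object.

    Markers are built per vessel (overlapping markers stay distinct) and
    clipped at the image edge; each carries its parent vessel's centroid,
    the anchor used for field assignment.
    """
    params = params or MorphometryParams()
    r_px = calibration.um_to_px(params.tmem_dilation_um)
    markers: list[TmemMarker] = []
    for v in tmem_set.ta_vessels:
        h, w = v.image_shape
        r0 = max(v.slices[0].start - r_px, 0)
        r1 = min(v.slices[0].stop + r_px, h)
        c0 = max(v.slices[1].start - r_px, 0)
        c1 = min(v.slices[1].stop + r_px, w)
        patch = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        pr = v.slices[0].start - r0
        pc = v.slices[1].start - c0
        patch[pr : pr + v.mask.shape[0], pc : pc + v.mask.shape[1]] = v.mask
        dist = ndimage.distance_transform_edt(~patch)
        marker_mask = dist <= r_px
        markers.append(
            TmemMarker(
                parent_id=v.id,
                parent_centroid=v.centroid(),
                slices=(slice(r0, r1), slice(c0, c1)),
                mask=marker_mask,
                area_um2=calibration.area_px_to_um2(int(marker_mask.sum())),
            )
        )
    tmem_set.markers = markers
    return tmem_set
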