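import numpy as np
import pytest

from tmemdp import morphometry
from tmemdp.morphometry import (
    DerivedLabel,
    MorphometryParams,
    ObjectClass,
    TissueObject,
    TMEMObjectSet,
    contact_fraction,
    filter_objects,
    form_objects,
    make_tmem_objects,
    reclassify_cascade,
)
from tmemdp.pixel_classifier import LabelScheme
from tmemdp.slide_io import CalibrationParams

from conftest import brute_contact_fraction

MPP1 = CalibrationParams(microns_per_pixel=1.0)
NO_SMOOTH = MorphometryParams(smoothing_radius_um=0.0)


def _stroma_map(h, w):
    return np.full((h, w), int(LabelScheme.STROMA), dtype=np.uint8)


def _make_object(mask, cls=ObjectClass.MACROPHAGE, mpp=1.0, image_shape=None, oid=1):
    """Wrap a full-image boolean mask into a measured TissueObject."""
    mask = np.asarray(mask, dtype=bool)
    image_shape = image_shape or mask.shape
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    calib = CalibrationParams(microns_per_pixel=mpp)
    return morphometry._measure(oid, cls, sl, mask[sl], calib, image_shape)


class TestFormObjects:
    def test_adjacent_dark_and_light_tumor_merge_into_one_object(self):
        lm = _stroma_map(20, 20)
        lm[5, 5] = LabelScheme.TUMOR_DARK
        lm[5, 6] = LabelScheme.TUMOR_LIGHT
        objs = form_objects(lm, MPP1, NO_SMOOTH)
        tumors = objs[ObjectClass.TUMOR]
        assert len(tumors) == 1
        assert tumors[0].n_pixels == 2

    def test_closing_bridges_subkernel_gap(self):
        lm = _stroma_map(30, 30)
        lm[10:15, 5:10] = LabelScheme.VESSEL
        lm[10:15, 11:16] = LabelScheme.VESSEL  # 1 px gap at col 10
        no_smooth = form_objects(lm, MPP1, NO_SMOOTH)
        smoothed = form_objects(lm, MPP1, MorphometryParams(smoothing_radius_um=1.0))
        assert len(no_smooth[ObjectClass.VESSEL]) == 2
        assert len(smoothed[ObjectClass.VESSEL]) == 1

    def test_object_area_equals_pixel_count_times_mpp_squared(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            lm = _stroma_map(40, 40)
            r, c = rng.integers(5, 25, size=2)
            h, w = rng.integers(2, 10, size=2)
            lm[r : r + h, c : c + w] = LabelScheme.MACROPHAGE
            mpp = float(rng.uniform(0.2, 1.5))
            calib = CalibrationParams(microns_per_pixel=mpp)
            objs = form_objects(lm, calib, NO_SMOOTH)
            mac = objs[ObjectClass.MACROPHAGE][0]
            assert mac.area_um2 == pytest.approx(h * w * mpp * mpp)

    def test_smoothing_resolves_overlap_with_vessel_priority(self):
        # closing the tumor mask fills its concavity around a vessel notch;
        # the overlap must resolve to VESSEL
        lm = _stroma_map(40, 40)
        lm[10:30, 10:30] = LabelScheme.TUMOR_DARK
        lm[18:22, 26:34] = LabelScheme.VESSEL  # bites a notch into the tumor
        objs = form_objects(lm, MPP1, MorphometryParams(smoothing_radius_um=2.0))
        vessel_px = sum(o.n_pixels for o in objs[ObjectClass.VESSEL])
        assert vessel_px == 4 * 8


class TestFilterObjects:
    @pytest.mark.parametrize(
        "cls,area,kept",
        [
            (ObjectClass.MACROPHAGE, 900.0, False),  # aggregate > 800 removed
            (ObjectClass.MACROPHAGE, 800.0, True),   # exactly 800 kept
            (ObjectClass.VESSEL, 801.0, False),
            (ObjectClass.VESSEL, 4.0, False),        # < 5 removed
            (ObjectClass.VESSEL, 5.0, True),         # exactly 5 kept
            (ObjectClass.MACROPHAGE, 4.0, False),
            (ObjectClass.MACROPHAGE, 5.0, True),
            (ObjectClass.TUMOR, 9.0, False),         # tumor fragment < 10
            (ObjectClass.TUMOR, 10.0, True),
            (ObjectClass.STROMA, 399.0, False),      # stroma < 400
            (ObjectClass.STROMA, 400.0, True),
        ],
    )
    def test_printed_area_boundaries_are_strict(self, cls, area, kept):
        n_px = int(round(area))  # 1 um/px -> area in um2 == pixel count
        side = int(np.ceil(np.sqrt(n_px)))
        mask = np.zeros((side + 2, side + 2), dtype=bool)
        filled = 0
        for r in range(side):
            for c in range(side):
                if filled < n_px:
                    mask[r + 1, c + 1] = True
                    filled += 1
        obj = _make_object(mask, cls=cls)
        assert obj.area_um2 == pytest.approx(area)
        result = filter_objects({cls: [obj]})
        assert (len(result[cls]) == 1) is kept

    def test_empty_object_set_stays_empty(self):
        result = filter_objects({c: [] for c in ObjectClass})
        assert all(len(v) == 0 for v in result.values())


class TestContactFraction:
    def test_fully_surrounded_object_has_contact_one(self):
        obj_mask = np.zeros((9, 9), dtype=bool)
        obj_mask[3:6, 3:6] = True
        neighbor = ~obj_mask
        obj = _make_object(obj_mask)
        assert contact_fraction(obj, neighbor) == 1.0

    def test_no_neighbor_anywhere_gives_zero(self):
        obj_mask = np.zeros((9, 9), dtype=bool)
        obj_mask[3:6, 3:6] = True
        obj = _make_object(obj_mask)
        assert contact_fraction(obj, np.zeros((9, 9), dtype=bool)) == 0.0

    def test_random_configurations_match_adjacency_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            h, w = rng.integers(5, 16, size=2)
            field = rng.random((h, w))
            obj_mask = field < 0.35
            neighbor = (field > 0.6) & ~obj_mask
            # take the largest connected component as the object
            from scipy import ndimage

            lab, n = ndimage.label(obj_mask, structure=np.ones((3, 3)))
            if n == 0:
                continue
            sizes = ndimage.sum_labels(obj_mask, lab, index=range(1, n + 1))
            comp = lab == (1 + int(np.argmax(sizes)))
            obj = _make_object(comp)
            expected = brute_contact_fraction(comp, neighbor)
            assert contact_fraction(obj, neighbor) == pytest.approx(expected)

    def test_boundary_count_matches_oracle_on_image_edge(self):
        # object touching the image edge: edge pixels are boundary pixels
        obj_mask = np.zeros((6, 6), dtype=bool)
        obj_mask[0:3, 0:3] = True
        obj = _make_object(obj_mask)
        from conftest import brute_boundary_pixels

        assert obj.boundary_px == len(brute_boundary_pixels(obj_mask))
        assert obj.boundary_px == 8  # 3x3 block: all but the center pixel


class TestCascade:
    def test_low_macrophage_contact_vessel_yields_empty_set(self):
        # 5x160 um2 vessel (exactly 800 um2, kept; 326 boundary px) touched
        # by a 2 px-wide macrophage: contact ~1.2%, below the 2% gate
        lm = _stroma_map(200, 200)
        lm[5:195, 5:195] = LabelScheme.TUMOR_LIGHT
        lm[50:55, 12:172] = LabelScheme.VESSEL
        lm[47:50, 40:42] = LabelScheme.MACROPHAGE
        objs = filter_objects(form_objects(lm, MPP1, NO_SMOOTH), NO_SMOOTH)
        vessel = objs[ObjectClass.VESSEL][0]
        assert vessel.area_um2 == 800.0
        mac_mask = morphometry.class_union_mask(
            objs[ObjectClass.MACROPHAGE], (200, 200)
        )
        assert 0 < contact_fraction(vessel, mac_mask) < 0.02
        result = reclassify_cascade(objs, NO_SMOOTH)
        assert result.ta_vessels == [] and result.ta_macrophages == []

    def test_small_macrophage_triad_passes_small_gates(self):
        # 30 um2 macrophage with >10% tumor and >10% vessel contact beside
        # a 15x15 vessel (the macrophage also covers >20% of the vessel
        # perimeter, so the vessel passes step d)
        lm = _stroma_map(60, 60)
        lm[5:55, 5:55] = LabelScheme.TUMOR_DARK
        lm[20:35, 20:35] = LabelScheme.VESSEL
        lm[22:32, 35:38] = LabelScheme.MACROPHAGE  # 10x3 = 30 px < 40 um2
        objs = filter_objects(form_objects(lm, MPP1, NO_SMOOTH), NO_SMOOTH)
        result = reclassify_cascade(objs, NO_SMOOTH)
        assert len(result.ta_vessels) == 1
        assert len(result.ta_macrophages_small) == 1
        assert result.ta_macrophages_large == []
        mac = result.ta_macrophages_small[0]
        assert mac.area_um2 < 40.0
        assert mac.contacts["tumor"] >= 0.10 and mac.contacts["vessel"] >= 0.10

    def test_small_path_requires_ten_percent_tumor_contact(self):
        # same geometry but tumor pulled back so the macrophage's tumor
        # contact drops below 10% -> no TA objects
        lm = _stroma_map(60, 60)
        lm[5:55, 5:55] = LabelScheme.TUMOR_DARK
        lm[20:35, 20:35] = LabelScheme.VESSEL
        lm[20:34, 35:40] = LabelScheme.STROMA  # stroma jacket around the mac
        lm[22:32, 35:38] = LabelScheme.MACROPHAGE
        objs = filter_objects(form_objects(lm, MPP1, NO_SMOOTH), NO_SMOOTH)
        mac = objs[ObjectClass.MACROPHAGE][0]
        tumor_mask = morphometry.class_union_mask(objs[ObjectClass.TUMOR], (60, 60))
        assert contact_fraction(mac, tumor_mask) < 0.10
        result = reclassify_cascade(objs, NO_SMOOTH)
        assert result.ta_macrophages == []
        assert result.ta_vessels == []

    def test_cascade_is_monotone_in_contact_thresholds(self):
        rng = np.random.default_rng(23)
        base = MorphometryParams(smoothing_radius_um=0.0)
        for seed in range(5):
            lm = _random_tissue_map(np.random.default_rng(seed), 80)
            objs = filter_objects(form_objects(lm, MPP1, base), base)
            n_base = _count_ta(reclassify_cascade(objs, base))
            raised = MorphometryParams(
                smoothing_radius_um=0.0,
                vessel_mac_contact_min=0.10,
                small_mac_tumor_contact_min=0.30,
                small_mac_vessel_contact_min=0.30,
                large_mac_tumor_contact_min=0.30,
                large_mac_vessel_contact_min=0.40,
                ta_vessel_tumor_contact_min=0.40,
                ta_vessel_mac_contact_min=0.40,
            )
            objs2 = filter_objects(form_objects(lm, MPP1, raised), raised)
            n_raised = _count_ta(reclassify_cascade(objs2, raised))
            assert n_raised <= n_base

    def test_every_ta_vessel_was_a_complex(self):
        lm = _stroma_map(60, 60)
        lm[5:55, 5:55] = LabelScheme.TUMOR_DARK
        lm[20:35, 20:35] = LabelScheme.VESSEL
        lm[22:32, 35:38] = LabelScheme.MACROPHAGE
        objs = filter_objects(form_objects(lm, MPP1, NO_SMOOTH), NO_SMOOTH)
        result = reclassify_cascade(objs, NO_SMOOTH)
        for v in result.ta_vessels:
            assert v.contacts["macrophage"] >= 0.02


def _count_ta(result: TMEMObjectSet) -> int:
    return len(result.ta_vessels) + len(result.ta_macrophages)


def _random_tissue_map(rng, side):
    lm = np.full((side, side), int(LabelScheme.STROMA), dtype=np.uint8)
    lm[5 : side - 5, 5 : side - 5] = LabelScheme.TUMOR_LIGHT
    for _ in range(6):
        r, c = rng.integers(8, side - 20, size=2)
        h, w = rng.integers(3, 14, size=2)
        cls = rng.choice([int(LabelScheme.VESSEL), int(LabelScheme.MACROPHAGE)])
        lm[r : r + h, c : c + w] = cls
    return lm


class TestTmemMarkers:
    def test_zero_ta_vessels_give_empty_marker_set(self):
        result = make_tmem_objects(TMEMObjectSet(), MPP1)
        assert result.markers == []

    def test_marker_diameter_is_vessel_plus_two_dilation_radii(self):
        # a 10 um diameter vessel dilated by 50 um -> ~110 um marker,
        # verified against a brute-force Euclidean distance computation
        shape = (140, 140)
        vessel_mask = np.zeros(shape, dtype=bool)
        yy, xx = np.mgrid[0:140, 0:140]
        vessel_mask[(yy - 70) ** 2 + (xx - 70) ** 2 <= 5**2] = True
        v = _make_object(vessel_mask, cls=ObjectClass.VESSEL)
        v.label = DerivedLabel.TA_VESSEL
        result = make_tmem_objects(TMEMObjectSet(ta_vessels=[v]), MPP1)
        marker = result.markers[0]
        full = np.zeros(shape, dtype=bool)
        full[marker.slices] = marker.mask
        widths = full.sum(axis=1)
        assert widths.max() == pytest.approx(110, abs=2)
        # brute-force: every marker pixel within 50 px of some vessel pixel
        vr, vc = np.nonzero(vessel_mask)
        mr, mc = np.nonzero(full)
        d2 = (mr[:, None] - vr[None, :]) ** 2 + (mc[:, None] - vc[None, :]) ** 2
        assert (d2.min(axis=1) <= 50**2).all()
        assert marker.area_um2 >= v.area_um2

    def test_two_ta_vessels_give_two_markers_with_distinct_parents(self):
        shape = (200, 200)
        masks = []
        for off in (60, 100):
            m = np.zeros(shape, dtype=bool)
            m[off : off + 8, off : off + 8] = True
            masks.append(m)
        vessels = [
            _make_object(m, cls=ObjectClass.VESSEL, oid=i + 1) for i, m in enumerate(masks)
        ]
        result = make_tmem_objects(TMEMObjectSet(ta_vessels=vessels), MPP1)
        assert len(result.markers) == 2
        assert result.markers[0].parent_id != result.markers[1].parent_id

    def test_pipeline_is_deterministic(self):
        rng = np.random.default_rng(31)
        lm = _random_tissue_map(rng, 100)
        runs = []
        for _ in range(2):
            objs = filter_objects(form_objects(lm, MPP1), MorphometryParams())
            res = make_tmem_objects(reclassify_cascade(objs), MPP1)
            runs.append(
                (
                    len(res.ta_vessels),
                    len(res.ta_macrophages),
                    [tuple(np.round(m.parent_centroid, 6)) for m in res.markers],
                )
            )
        assert runs[0] == runs[1]
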