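"""Segmentation chain: each stage against small constructions and, for
Sauvola, a direct double-loop oracle."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.filters import threshold_sauvola as skimage_sauvola

from vesiph import (
    Image2D,
    LabelMap,
    SegmentationParams,
    VesicleMeasurement,
    apply_roi_corrections,
    extract_measurements,
    field_mask,
    generate_vesicle_scene,
    measure_scene,
    quantify_uptake,
    sauvola_threshold,
    size_filter,
    subtract_background,
    watershed_split,
)

from conftest import noiseless_params


def sauvola_direct(px, w, k, rdyn):
    """Naive per-pixel evaluation of the Sauvola criterion with truncated
    edge windows; the independent oracle for the integral-image version."""
    h, wd = px.shape
    half = w // 2
    out = np.zeros(px.shape, dtype=bool)
    for i in range(h):
        for j in range(wd):
            win = px[max(0, i - half): i + half + 1, max(0, j - half): j + half + 1]
            m = win.mean()
            s = win.std()
            out[i, j] = px[i, j] > m * (1.0 + k * (s / rdyn - 1.0))
    return out


def disk_image(shape, centers, radius, value=100.0):
    img = np.zeros(shape)
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    for r0, c0 in centers:
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = value
    return img


class TestSubtractBackground:
    @pytest.mark.parametrize(
        "pixels,bg,expected",
        [
            ([[10, 12], [8, 10]], 9.0, [[1, 3], [0, 1]]),
            ([[10, 12], [8, 10]], 0.0, [[10, 12], [8, 10]]),
            ([[9, 9], [9, 9]], 9.0, [[0, 0], [0, 0]]),
        ],
    )
    def test_mean_subtraction_with_clipping(self, pixels, bg, expected):
        # embed the 2x2 test patch beside a constant cell-free strip of value bg
        patch = np.array(pixels, dtype=float)
        bigger = np.zeros((2, 4))
        bigger[:, :2] = patch
        bigger[:, 2:] = bg
        region = np.zeros((2, 4), dtype=bool)
        region[:, 2:] = True
        out = subtract_background(Image2D(bigger), region)
        assert np.array_equal(out.pixels[:, :2], np.array(expected, dtype=float))

    def test_rectangle_region(self):
        img = Image2D(np.array([[5.0, 5.0, 1.0], [5.0, 5.0, 1.0]]))
        out = subtract_background(img, (0, 2, 2, 3))
        assert np.array_equal(out.pixels[:, 0], [4.0, 4.0])

    def test_empty_region_rejected(self):
        img = Image2D(np.ones((4, 4)))
        with pytest.raises(ValueError, match="empty"):
            subtract_background(img, np.zeros((4, 4), dtype=bool))


class TestFieldMask:
    def test_all_zero_image_rejected(self):
        with pytest.raises(ValueError, match="no cell field"):
            field_mask(Image2D(np.zeros((10, 10))), 0.5)

    def test_single_blob_recovered(self):
        img = Image2D(disk_image((30, 30), [(15, 15)], 6))
        mask = field_mask(img, 50.0)
        assert np.array_equal(mask, img.pixels > 50.0)

    def test_largest_component_wins(self):
        img = disk_image((60, 60), [(15, 15)], 10)
        img += disk_image((60, 60), [(45, 45)], 3)
        mask = field_mask(Image2D(img), 50.0)
        lab, n = ndimage.label(mask)
        assert n == 1
        assert mask[15, 15] and not mask[45, 45]

    def test_fractional_threshold_scales_with_max(self):
        img = Image2D(disk_image((20, 20), [(10, 10)], 4, value=200.0))
        assert np.array_equal(field_mask(img, 0.5), img.pixels > 100.0)


class TestSauvola:
    def test_all_zero_image_has_empty_foreground(self):
        img = Image2D(np.zeros((20, 20)))
        fg = sauvola_threshold(img, SegmentationParams(sauvola_rdyn=128.0))
        assert not fg.any()

    def test_k_zero_reduces_to_local_mean(self, rng):
        px = rng.uniform(0, 255, (32, 32))
        params = SegmentationParams(sauvola_k=0.0, sauvola_rdyn=128.0,
                                    sauvola_window_px=7)
        fg = sauvola_threshold(Image2D(px), params)
        expected = sauvola_direct(px, 7, 0.0, 128.0)  # reduces to px > m(x, y)
        assert np.array_equal(fg, expected)

    def test_single_bright_pixel_matches_direct_evaluation(self):
        px = np.zeros((15, 15))
        px[7, 7] = 100.0
        params = SegmentationParams(sauvola_window_px=5, sauvola_k=0.2,
                                    sauvola_rdyn=128.0)
        fg = sauvola_threshold(Image2D(px), params)
        assert np.array_equal(fg, sauvola_direct(px, 5, 0.2, 128.0))

    def test_integral_image_matches_double_loop_on_random_images(self, rng):
        params = SegmentationParams(sauvola_window_px=9, sauvola_k=0.3,
                                    sauvola_rdyn=100.0)
        for _ in range(5):
            px = rng.uniform(0, 255, (48, 40))
            fg = sauvola_threshold(Image2D(px), params)
            assert np.array_equal(fg, sauvola_direct(px, 9, 0.3, 100.0))

    def test_interior_agrees_with_skimage_reference(self, rng):
        # skimage pads by reflection, so only interior pixels are comparable
        px = rng.uniform(0, 255, (64, 64))
        w, k, r = 15, 0.2, 128.0
        params = SegmentationParams(sauvola_window_px=w, sauvola_k=k, sauvola_rdyn=r)
        ours = sauvola_threshold(Image2D(px), params)
        ref = px > skimage_sauvola(px, window_size=w, k=k, r=r)
        h = w // 2
        assert np.array_equal(ours[h:-h, h:-h], ref[h:-h, h:-h])

    def test_field_restricts_foreground(self):
        px = disk_image((40, 40), [(10, 10), (30, 30)], 4)
        params = SegmentationParams(sauvola_rdyn=128.0)
        field = np.zeros((40, 40), dtype=bool)
        field[:20, :20] = True
        fg = sauvola_threshold(Image2D(px), params, field=field)
        assert fg[:20, :20].any() and not fg[20:, 20:].any()

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="window"):
            sauvola_threshold(
                Image2D(np.zeros((5, 5))), SegmentationParams(sauvola_window_px=7)
            )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(sauvola_window_px=4)
        with pytest.raises(ValueError):
            SegmentationParams(sauvola_k=1.5)
        with pytest.raises(ValueError):
            SegmentationParams(size_min_px=10, size_max_px=5)


class TestWatershedSplit:
    def test_disjoint_disks_match_connected_components(self, seg_params):
        mask = disk_image((60, 60), [(15, 15), (45, 45)], 6) > 0
        labels = watershed_split(mask, None, seg_params)
        assert labels.n_labels == 2
        lab_cc, _ = ndimage.label(mask)
        # identical partition up to label naming
        assert np.array_equal(labels.labels > 0, mask)
        for lid in (1, 2):
            support = labels.labels == lid
            assert np.unique(lab_cc[support]).size == 1

    def test_single_disk_single_label(self, seg_params):
        mask = disk_image((30, 30), [(15, 15)], 7) > 0
        labels = watershed_split(mask, None, seg_params)
        assert labels.n_labels == 1
        assert np.array_equal(labels.labels == 1, mask)

    def test_touching_disks_split_near_equal_areas(self, seg_params):
        # centers 1.5 radii apart -> one fused blob the watershed must split
        r = 8
        mask = disk_image((50, 70), [(25, 28), (25, 40)], r) > 0
        lab_cc, n_cc = ndimage.label(mask)
        assert n_cc == 1
        labels = watershed_split(mask, None, seg_params)
        assert labels.n_labels == 2
        disk_area = np.pi * r**2
        areas = labels.areas()[1:]
        assert np.all(np.abs(areas - disk_area) <= 0.15 * disk_area)

    def test_every_foreground_pixel_labeled(self, seg_params):
        mask = disk_image((60, 60), [(20, 20), (27, 27), (45, 15)], 6) > 0
        labels = watershed_split(mask, None, seg_params)
        assert np.array_equal(labels.labels > 0, mask)

    def test_empty_mask_rejected(self, seg_params):
        with pytest.raises(ValueError):
            watershed_split(np.zeros((10, 10), dtype=bool), None, seg_params)


class TestSizeFilter:
    def make_labels(self):
        labels = np.zeros((30, 60), dtype=np.int32)
        labels[0, :2] = 1           # area 2
        labels[5:7, 5:10] = 2       # area 10
        labels[10:30, 30:50] = 3    # area 400
        return labels

    def test_area_bounds_drop_small_and_large(self):
        params = SegmentationParams(size_min_px=4, size_max_px=300)
        out = size_filter(LabelMap(self.make_labels()), params)
        assert out.n_labels == 1
        assert out.areas()[1] == 10

    def test_idempotent(self):
        params = SegmentationParams(size_min_px=4, size_max_px=300)
        once = size_filter(LabelMap(self.make_labels()), params)
        twice = size_filter(once, params)
        assert np.array_equal(once.labels, twice.labels)

    def test_wide_bounds_identity_up_to_renumbering(self):
        params = SegmentationParams(size_min_px=1, size_max_px=10**9)
        labels = self.make_labels()
        out = size_filter(LabelMap(labels), params)
        assert np.array_equal(out.labels > 0, labels > 0)
        assert out.n_labels == 3

    def test_empty_map_passes_through(self):
        out = size_filter(LabelMap(np.zeros((5, 5), dtype=np.int32)),
                          SegmentationParams())
        assert out.n_labels == 0

    def test_never_increases_foreground_after_watershed(self, seg_params):
        mask = disk_image((60, 60), [(15, 15), (45, 45)], 6) > 0
        labels = watershed_split(mask, None, seg_params)
        filtered = size_filter(labels, seg_params)
        assert (filtered.labels > 0).sum() <= (labels.labels > 0).sum()


class TestRoiCorrections:
    def make_labels(self):
        labels = np.zeros((20, 20), dtype=np.int32)
        labels[2:5, 2:5] = 1
        labels[2:5, 5:8] = 2
        labels[10:14, 10:14] = 3
        return LabelMap(labels)

    def test_empty_edit_list_is_identity(self):
        lm = self.make_labels()
        out = apply_roi_corrections(lm, [])
        assert np.array_equal(out.labels, lm.labels)

    def test_delete_renumbers_contiguously(self):
        out = apply_roi_corrections(self.make_labels(), [{"op": "delete", "label": 2}])
        assert out.n_labels == 2
        assert sorted(np.unique(out.labels)) == [0, 1, 2]

    def test_merge_adjacent_sums_areas(self):
        lm = self.make_labels()
        a1 = (lm.labels == 1).sum() + (lm.labels == 2).sum()
        out = apply_roi_corrections(lm, [{"op": "merge", "labels": [1, 2]}])
        assert out.n_labels == 2
        assert out.areas()[1] == a1

    def test_add_polygon_creates_label(self):
        out = apply_roi_corrections(
            self.make_labels(),
            [{"op": "add_polygon", "vertices": [[16, 2], [16, 6], [19, 6], [19, 2]]}],
        )
        assert out.n_labels == 4

    def test_missing_id_named_in_error(self):
        with pytest.raises(ValueError, match="99"):
            apply_roi_corrections(self.make_labels(), [{"op": "delete", "label": 99}])

    def test_edits_loadable_from_json_file(self, tmp_path):
        p = tmp_path / "edits.json"
        p.write_text('[{"op": "delete", "label": 1}]')
        out = apply_roi_corrections(self.make_labels(), p)
        assert out.n_labels == 2
        assert "edit:delete" in out.provenance


class TestExtractMeasurements:
    def test_uniform_label_mean_and_area(self):
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[1:4, 1:5] = 1  # 12 px
        img = Image2D(np.full((6, 6), 5.0), channel_tag="R")
        (m,) = extract_measurements(LabelMap(labels), [img])
        assert m.area_px == 12
        assert m.mean_intensity["R"] == pytest.approx(5.0)
        assert m.centroid == pytest.approx((2.0, 2.5))

    def test_channel_recall_preserves_ratio(self, rng):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[2:5, 2:5] = 1
        labels[6:9, 6:9] = 2
        base = rng.uniform(1, 10, (10, 10))
        r = Image2D(base, channel_tag="R")
        o = Image2D(2 * base, channel_tag="O")
        ms = extract_measurements(LabelMap(labels), [o, r])
        for m in ms:
            assert m.mean_intensity["O"] / m.mean_intensity["R"] == pytest.approx(2.0)

    def test_shape_mismatch_rejected(self):
        labels = LabelMap(np.zeros((5, 5), dtype=np.int32))
        with pytest.raises(ValueError):
            extract_measurements(labels, [Image2D(np.zeros((4, 4)))])

    def test_noiseless_scene_means_match_ground_truth(self, fixture):
        params = noiseless_params(n_vesicles=15, vesicle_ph_spec=6.8, seed=5)
        o, r, truth = generate_vesicle_scene(params, fixture)
        labels = np.zeros(o.shape, dtype=np.int32)
        rr = np.arange(o.shape[0])[:, None]
        cc = np.arange(o.shape[1])[None, :]
        for obj in truth.objects:
            inside = (rr - obj.center[0]) ** 2 + (cc - obj.center[1]) ** 2 <= obj.radius_px**2
            labels[inside] = obj.id + 1
        ms = extract_measurements(LabelMap(labels), [o, r])
        by_id = {m.label_id: m for m in ms}
        for obj in truth.objects:
            m = by_id[obj.id + 1]
            assert m.mean_intensity["O"] == pytest.approx(obj.expected_mean_o, rel=1e-9)
            assert m.mean_intensity["R"] == pytest.approx(obj.expected_mean_r, rel=1e-9)


class TestQuantifyUptake:
    def mk(self, means):
        return [
            VesicleMeasurement(i + 1, 10, (0, 0), {"R": v}) for i, v in enumerate(means)
        ]

    def test_single_worm_mean(self):
        table = quantify_uptake({"cond": [self.mk([10, 20, 30])]})
        assert table.loc[0, "mean_intensity"] == pytest.approx(20.0)
        assert table.loc[0, "n_vesicles"] == 3
        assert table.loc[0, "n_worms"] == 1

    def test_sem_across_worms(self):
        table = quantify_uptake({"c": [self.mk([10, 10]), self.mk([20, 20])]})
        # per-worm means 10 and 20 -> sem = sd/sqrt(2) = 5
        assert table.loc[0, "sem"] == pytest.approx(5.0)

    def test_empty_condition_reports_zero_with_warning(self):
        with pytest.warns(UserWarning, match="zero vesicles"):
            table = quantify_uptake({"empty": [[]]})
        assert table.loc[0, "mean_intensity"] == 0.0
        assert table.loc[0, "n_vesicles"] == 0

    def test_no_images_rejected(self):
        with pytest.raises(ValueError):
            quantify_uptake({"c": []})


class TestSegmentationRecovery:
    def test_noiseless_scene_recovered_exactly_once_each(self, fixture, seg_params):
        """Every ground-truth vesicle yields exactly one label (centroid
        within one radius) and no spurious labels appear."""
        params = noiseless_params(
            n_vesicles=60, vesicle_ph_spec=6.8, seed=7,
            psf_sigma_um=0.15, background_o=10.0, background_r=10.0,
        )
        o, r, truth = generate_vesicle_scene(params, fixture)
        labels, _ = measure_scene(o, r, seg_params)
        cents = np.array(
            ndimage.center_of_mass(
                labels.labels > 0, labels.labels, np.arange(1, labels.n_labels + 1)
            )
        )
        truth_c = np.array([ob.center for ob in truth.objects])
        radii = np.array([ob.radius_px for ob in truth.objects])
        d = np.linalg.norm(truth_c[:, None, :] - cents[None, :, :], axis=2)
        matched = d <= radii[:, None]
        assert (matched.sum(axis=1) == 1).all(), "every vesicle found exactly once"
        assert (matched.sum(axis=0) == 1).all(), "no spurious labels"

    def test_pipeline_deterministic(self, fixture, seg_params):
        params = noiseless_params(n_vesicles=30, seed=3, psf_sigma_um=0.15)
        o, r, _ = generate_vesicle_scene(params, fixture)
        l1, _ = measure_scene(o, r, seg_params)
        l2, _ = measure_scene(o, r, seg_params)
        assert np.array_equal(l1.labels, l2.labels)
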