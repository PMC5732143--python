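"""Segmentation correctness and P2A shape-statistic calibration."""

import numpy as np
import pytest
from scipy.integrate import quad

from spherohca.exceptions import NoObjectError
from spherohca.geometry import AcquisitionGeometry
from spherohca.segmentation import (
    AreaFilter,
    ObjectMask,
    apply_area_filter,
    compute_morphometrics,
    estimate_sphere_volume,
    perimeter_um,
    segment_brightfield,
    shape_p2a,
)

from .conftest import disk_mask, ellipse_mask


def _mask_from_binary(binary):
    from scipy import ndimage as ndi

    labels, n = ndi.label(binary)
    areas = ndi.sum_labels(np.ones_like(labels), labels, range(1, n + 1)).astype(int)
    return ObjectMask(mask=labels > 0, labels=labels.astype(np.int32),
                      areas_px2=list(areas))


def ellipse_perimeter(a, b):
    e2 = 1 - (b / a) ** 2
    return 4 * a * quad(lambda t: np.sqrt(1 - e2 * np.sin(t) ** 2), 0, np.pi / 2)[0]


class TestSegmentation:
    def test_noise_free_disk_iou(self, clean_well, geometry):
        _, images, truth = clean_well
        mask = apply_area_filter(
            segment_brightfield(images["brightfield"], geometry), AreaFilter(1000)
        )
        sel = mask.selected_mask()
        iou = (sel & truth.mask).sum() / (sel | truth.mask).sum()
        assert iou >= 0.95

    def test_noisy_disk_iou(self, noisy_well, geometry):
        _, images, truth = noisy_well
        mask = apply_area_filter(
            segment_brightfield(images["brightfield"], geometry), AreaFilter(1000)
        )
        sel = mask.selected_mask()
        iou = (sel & truth.mask).sum() / (sel | truth.mask).sum()
        assert iou >= 0.95

    def test_blank_image_yields_empty_mask(self, geometry):
        rng = np.random.default_rng(0)
        blank = rng.normal(32000, 200, geometry.shape).astype(np.uint16)
        assert segment_brightfield(blank, geometry).object_count == 0
        uniform = np.full(geometry.shape, 30000, dtype=np.uint16)
        assert segment_brightfield(uniform, geometry).object_count == 0

    def test_satellite_below_filter_not_selected(self, geometry):
        from spherohca.simulate import SpheroidPhenotypeParams, render_well

        p = SpheroidPhenotypeParams(
            seeded_cells=2000, disruption="fragmentation", noise_sd=0.0
        )
        images, truth = render_well(p, geometry, 0.0, seed=9)
        mask = segment_brightfield(images["brightfield"], geometry)
        assert mask.object_count >= 2
        filtered = apply_area_filter(mask, AreaFilter(1000))
        # only the main disk survives and is selected
        assert filtered.object_count == 1
        assert filtered.selected_mask().sum() == max(mask.areas_px2)

    def test_determinism(self, noisy_well, geometry):
        _, images, _ = noisy_well
        a = segment_brightfield(images["brightfield"], geometry)
        b = segment_brightfield(images["brightfield"], geometry)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestAreaFilter:
    def test_threshold_straddling(self):
        binary = np.zeros((200, 200), bool)
        binary[10:40, 10:40] = True  # 900 px^2 < 1000
        binary[60:110, 60:110] = True  # 2500 px^2
        filtered = apply_area_filter(_mask_from_binary(binary), AreaFilter(1000))
        assert filtered.object_count == 1
        assert filtered.areas_px2 == [2500]

    def test_zero_threshold_keeps_all(self):
        binary = np.zeros((100, 100), bool)
        binary[5:10, 5:10] = True
        binary[50:60, 50:60] = True
        filtered = apply_area_filter(_mask_from_binary(binary), AreaFilter(0))
        assert filtered.object_count == 2

    def test_all_below_threshold_flagged_empty(self):
        binary = np.zeros((100, 100), bool)
        binary[5:10, 5:10] = True
        filtered = apply_area_filter(_mask_from_binary(binary), AreaFilter(1000))
        assert filtered.selected_object is None
        with pytest.raises(NoObjectError):
            filtered.selected_mask()


class TestShapeP2A:
    def test_analytic_circle_is_one(self):
        for r in (1.0, 57.3, 400.0):
            assert shape_p2a(2 * np.pi * r, np.pi * r**2) == pytest.approx(1.0)

    def test_analytic_ellipse_2to1(self):
        a, b = 200.0, 100.0
        p2a = shape_p2a(ellipse_perimeter(a, b), np.pi * a * b)
        assert p2a == pytest.approx(1.19, abs=0.01)

    def test_rasterized_disk_r100_calibration(self, geometry):
        rec = compute_morphometrics(
            apply_area_filter(_mask_from_binary(disk_mask(100)), AreaFilter(0)),
            geometry,
        )
        assert 0.98 <= rec.shape_p2a <= 1.05

    def test_p2a_error_decreases_with_radius(self, geometry):
        errs = []
        for r in (25, 50, 100, 200):
            rec = compute_morphometrics(
                apply_area_filter(_mask_from_binary(disk_mask(r)), AreaFilter(0)),
                geometry,
            )
            errs.append(abs(rec.shape_p2a - 1.0))
        assert errs == sorted(errs, reverse=True)

    def test_isoperimetric_monotonicity_in_elongation(self, geometry):
        p2as = []
        for ratio in (1, 2, 4):
            a = 80 * np.sqrt(ratio)
            rec = compute_morphometrics(
                apply_area_filter(
                    _mask_from_binary(ellipse_mask(a, 80**2 / a)), AreaFilter(0)
                ),
                geometry,
            )
            p2as.append(rec.shape_p2a)
        assert p2as[0] < p2as[1] < p2as[2]

    def test_scale_equivariance(self):
        binary = disk_mask(60)
        mask = apply_area_filter(_mask_from_binary(binary), AreaFilter(0))
        g1 = AcquisitionGeometry(fov_um=100.0, image_px=binary.shape[0])
        g2 = AcquisitionGeometry(fov_um=300.0, image_px=binary.shape[0])
        r1 = compute_morphometrics(mask, g1)
        r2 = compute_morphometrics(mask, g2)
        assert r2.area_um2 == pytest.approx(9 * r1.area_um2)
        assert r2.perimeter_um == pytest.approx(3 * r1.perimeter_um)
        assert r2.shape_p2a == pytest.approx(r1.shape_p2a)


class TestVolume:
    def test_closed_form_sphere_volume(self):
        from spherohca.segmentation import MorphometricRecord

        record = MorphometricRecord(
            area_px2=1, area_um2=1.0, perimeter_um=1.0, shape_p2a=1.0,
            circ_diameter_um=400.0, sphere_volume_pl=0.0,
            aspect_ratio_lwr=1.0, centroid_um=(0, 0),
        )
        assert estimate_sphere_volume(record) == pytest.approx(33510, rel=1e-3)

    def test_zero_diameter_errors(self):
        from spherohca.segmentation import MorphometricRecord

        record = MorphometricRecord(
            area_px2=0, area_um2=0.0, perimeter_um=0.0, shape_p2a=1.0,
            circ_diameter_um=0.0, sphere_volume_pl=0.0,
            aspect_ratio_lwr=1.0, centroid_um=(0, 0),
        )
        with pytest.raises(NoObjectError):
            estimate_sphere_volume(record)

    def test_rasterized_disk_volume_within_5pct(self, geometry):
        r_px = 110
        rec = compute_morphometrics(
            apply_area_filter(_mask_from_binary(disk_mask(r_px)), AreaFilter(0)),
            geometry,
        )
        r_um = r_px * geometry.pixel_size_um
        analytic_pl = (4 / 3) * np.pi * r_um**3 / 1000.0
        assert rec.sphere_volume_pl == pytest.approx(analytic_pl, rel=0.05)

    def test_union_mode_measures_all_objects(self, geometry):
        binary = np.zeros((300, 300), bool)
        binary[20:120, 20:120] = True
        binary[200:260, 200:260] = True
        mask = apply_area_filter(_mask_from_binary(binary), AreaFilter(0))
        largest = compute_morphometrics(mask, geometry, mode="largest")
        union = compute_morphometrics(mask, geometry, mode="union")
        assert union.area_px2 == 100 * 100 + 60 * 60
        assert largest.area_px2 == 100 * 100
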