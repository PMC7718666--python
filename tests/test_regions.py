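"""Annulus/FAZ geometry and the outcome metrics against analytic oracles."""

import logging

import numpy as np
import pytest

from octaquant import regions, synthetic, vessels
from octaquant.io import FazPolygon
from octaquant.regions import AnnulusSpec
from octaquant.vessels import SkeletonMap

MMPP = 3.0 / 245.0
CENTER = (122 * MMPP, 122 * MMPP)
ANNULUS_AREA = np.pi * (1.25**2 - 0.5**2)  # 4.123 mm^2


def _circle(radius, center=CENTER, n=256):
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return FazPolygon(
        np.column_stack(
            [center[0] + radius * np.cos(phi), center[1] + radius * np.sin(phi)]
        )
    )


class TestAnnulusMask:
    def test_area_matches_analytic(self):
        mask = regions.annulus_mask(AnnulusSpec(CENTER), (245, 245), MMPP)
        assert mask.sum() * MMPP**2 == pytest.approx(ANNULUS_AREA, rel=0.01)

    def test_membership_by_radius(self):
        mask = regions.annulus_mask(AnnulusSpec(CENTER), (245, 245), MMPP)

        def at(radius_mm):
            col = int(round((CENTER[0] + radius_mm) / MMPP))
            row = int(round(CENTER[1] / MMPP))
            return mask[row, col]

        assert not at(0.3)
        assert at(0.6)
        assert not at(1.4)

    def test_translation_equivariance(self):
        m0 = regions.annulus_mask(AnnulusSpec(CENTER), (245, 245), MMPP)
        shift = 7
        c2 = (CENTER[0] + shift * MMPP, CENTER[1])
        m1 = regions.annulus_mask(AnnulusSpec(c2), (245, 245), MMPP)
        assert np.array_equal(np.roll(m0, shift, axis=1)[:, shift:], m1[:, shift:])

    def test_annulus_outside_field_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            regions.annulus_mask(AnnulusSpec((0.2, 0.2)), (245, 245), MMPP)
        with pytest.raises(ValueError):
            AnnulusSpec(CENTER, inner_radius_mm=1.5, outer_radius_mm=1.0)

    def test_resolution_convergence(self):
        # error < 0.2% at 4x resolution
        n = 980
        mmpp = 3.0 / n
        c = ((n - 1) / 2 * mmpp, (n - 1) / 2 * mmpp)
        mask = regions.annulus_mask(AnnulusSpec(c), (n, n), mmpp)
        assert mask.sum() * mmpp**2 == pytest.approx(ANNULUS_AREA, rel=0.002)


class TestFazGeometry:
    def test_unit_square_centroid(self):
        poly = FazPolygon([[0, 0], [1, 0], [1, 1], [0, 1]])
        assert regions.faz_center(poly) == pytest.approx((0.5, 0.5))

    def test_translated_centroid(self):
        poly = FazPolygon([[2, 3], [3, 3], [3, 4], [2, 4]])
        assert regions.faz_center(poly) == pytest.approx((2.5, 3.5))

    def test_l_shaped_hexagon_centroid(self):
        # two rectangles: (0,0)-(2,1) area 2 at (1, .5); (0,1)-(1,2) area 1
        # at (.5, 1.5) -> centroid (5/6, 5/6)
        poly = FazPolygon([[0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]])
        assert regions.faz_center(poly) == pytest.approx((5 / 6, 5 / 6))

    def test_square_area(self):
        assert regions.faz_area(FazPolygon([[0, 0], [1, 0], [1, 1], [0, 1]])) == pytest.approx(1.0)

    def test_reversed_vertex_order_same_area(self):
        fwd = FazPolygon([[0, 0], [1, 0], [1, 1], [0, 1]])
        rev = FazPolygon(fwd.vertices[::-1])
        assert regions.faz_area(fwd) == regions.faz_area(rev)

    def test_regular_64gon_area(self):
        assert regions.faz_area(_circle(0.5, n=64)) == pytest.approx(
            0.5 * 64 * 0.25 * np.sin(2 * np.pi / 64)
        )


class TestMeasurementRegion:
    def test_faz_inside_inner_disk_leaves_annulus(self):
        ann = regions.annulus_mask(AnnulusSpec(CENTER), (245, 245), MMPP)
        small = _circle(0.31)  # typical SCP FAZ fits inside the 0.5 mm inner disk
        reg = regions.measurement_region(ann, small, MMPP)
        assert np.array_equal(reg.mask, ann)

    def test_large_faz_carves_ring(self):
        ann = regions.annulus_mask(AnnulusSpec(CENTER), (245, 245), MMPP)
        reg = regions.measurement_region(ann, _circle(0.6), MMPP)
        expect = ANNULUS_AREA - np.pi * (0.6**2 - 0.5**2)
        assert reg.area_mm2 == pytest.approx(expect, rel=0.01)

    def test_no_polygon_warns_and_equals_annulus(self, caplog):
        ann = regions.annulus_mask(AnnulusSpec(CENTER), (245, 245), MMPP)
        with caplog.at_level(logging.WARNING):
            reg = regions.measurement_region(ann, None, MMPP)
        assert np.array_equal(reg.mask, ann)
        assert any("FAZ" in r.message for r in caplog.records)


class TestVesselDensity:
    def _region(self):
        ann = regions.annulus_mask(AnnulusSpec(CENTER), (245, 245), MMPP)
        return regions.measurement_region(ann, None, MMPP)

    def test_empty_skeleton_zero(self):
        reg = self._region()
        sk = SkeletonMap(np.zeros((245, 245), bool), 0.0)
        assert regions.vessel_density(sk, reg) == 0.0

    def test_horizontal_chord_through_center(self):
        # in-region chord length 2 x (1.25 - 0.5) = 1.5 mm
        reg = self._region()
        skel = np.zeros((245, 245), bool)
        skel[122, :] = True
        sk = SkeletonMap(skel, 0.0)
        assert regions.vessel_density(sk, reg) == pytest.approx(1.5 / ANNULUS_AREA, rel=0.05)

    def test_generator_truth_recovery(self, default_scene):
        t = default_scene
        mmpp = t.params.mm_per_pixel
        ann = regions.annulus_mask(
            AnnulusSpec(regions.faz_center(t.faz_polygon)), t.vessel_mask.shape, mmpp
        )
        reg = regions.measurement_region(ann, t.faz_polygon, mmpp)
        sk = vessels.skeletonize(vessels.binarize(t.image.intensities).mask, mm_per_pixel=mmpp)
        vd = regions.vessel_density(sk, reg)
        truth_len = vessels.estimate_skeleton_length(t.centerline_mask & reg.mask, mmpp)
        assert vd == pytest.approx(truth_len / reg.area_mm2, rel=0.05)

    def test_invariant_to_pixels_outside_region(self):
        reg = self._region()
        skel = np.zeros((245, 245), bool)
        skel[122, :] = True
        base = regions.vessel_density(SkeletonMap(skel, 0.0), reg)
        skel2 = skel.copy()
        skel2[2, :] = True  # far outside the annulus
        assert regions.vessel_density(SkeletonMap(skel2, 0.0), reg) == base


class TestPerfusionDensity:
    def _region(self):
        ann = regions.annulus_mask(AnnulusSpec(CENTER), (245, 245), MMPP)
        return regions.measurement_region(ann, None, MMPP)

    def test_empty_mask_zero(self):
        assert regions.large_vessel_perfusion_density(np.zeros((245, 245), bool), self._region()) == 0

    def test_full_mask_hundred(self):
        assert regions.large_vessel_perfusion_density(np.ones((245, 245), bool), self._region()) == 100

    def test_known_fraction_band(self):
        reg = self._region()
        band = np.zeros((245, 245), bool)
        band[110:135, :] = True
        expect = 100.0 * (band & reg.mask).sum() / reg.mask.sum()
        got = regions.large_vessel_perfusion_density(band, reg)
        assert got == pytest.approx(expect, abs=1.0)

    def test_monotone_under_addition_inside_region(self):
        reg = self._region()
        a = np.zeros((245, 245), bool)
        a[110:120, :] = True
        b = a.copy()
        b[130:135, :] = True
        assert regions.large_vessel_perfusion_density(
            b, reg
        ) >= regions.large_vessel_perfusion_density(a, reg)


class TestFractalDimension:
    def test_filled_region_plane(self):
        full = np.ones((245, 245), bool)
        assert regions.fractal_dimension_boxcount(full) == pytest.approx(2.0, abs=0.05)

    def test_straight_line_curve(self):
        line = np.zeros((245, 245), bool)
        line[120, :] = True
        assert regions.fractal_dimension_boxcount(line) == pytest.approx(1.0, abs=0.05)

    def test_sierpinski_carpet(self):
        m = np.ones((1, 1), bool)
        for _ in range(5):
            z = np.zeros_like(m)
            m = np.block([[m, m, m], [m, z, m], [m, m, m]])
        assert m.shape == (243, 243)
        assert regions.fractal_dimension_boxcount(m) == pytest.approx(
            np.log(8) / np.log(3), abs=0.05
        )

    def test_union_with_self_idempotent(self):
        line = np.zeros((245, 245), bool)
        line[120, :] = True
        assert regions.fractal_dimension_boxcount(line | line) == regions.fractal_dimension_boxcount(line)

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            regions.fractal_dimension_boxcount(np.zeros((245, 245), bool))


class TestComputeMetricRecord:
    def test_scene_pair_components_within_tolerance(self, scene_pair):
        scp, dcp = scene_pair
        rec = regions.compute_metric_record(
            scp.image, dcp.image, scp.faz_polygon, dcp.faz_polygon
        )
        assert rec.faz_area_scp == pytest.approx(0.31, rel=0.05)
        assert rec.faz_area_dcp == pytest.approx(1.11, rel=0.05)
        assert rec.vd_scp > 0 and rec.vd_dcp > 0
        assert 0.9 <= rec.fd_scp <= 2.1 and 0.9 <= rec.fd_dcp <= 2.1
        assert 0 <= rec.pd_large_scp <= 100

    def test_identical_inputs_identical_metrics(self, scene_pair):
        scp, _ = scene_pair
        twin = regions.compute_metric_record(scp.image, scp.image, scp.faz_polygon, scp.faz_polygon)
        assert twin.vd_scp == twin.vd_dcp
        assert twin.fd_scp == twin.fd_dcp

    def test_missing_dcp_gives_partial_record(self, scene_pair):
        scp, _ = scene_pair
        rec = regions.compute_metric_record(scp.image, None, scp.faz_polygon, None)
        assert rec.vd_scp is not None
        assert rec.vd_dcp is None and rec.fd_dcp is None and rec.faz_area_dcp is None

    def test_no_images_rejected(self):
        with pytest.raises(ValueError):
            regions.compute_metric_record(None, None)
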