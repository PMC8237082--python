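import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gakinetics as gk
from gakinetics.lesion import MarginContour


class TestLoadMask:
    def test_empty_mask_has_zero_area(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "empty.png"
        iio.imwrite(path, np.zeros((500, 500), dtype=np.uint8))
        mask = gk.load_lesion_mask(path, 12.0)
        assert mask.pixel_area_mm2 == 0.0
        assert gk.extract_margins(mask) == []

    def test_physical_extent_of_standard_raster(self, tmp_path):
        import imageio.v3 as iio

        path = tmp_path / "m.png"
        img = np.zeros((500, 500), dtype=np.uint8)
        img[200:300, 200:300] = 255
        iio.imwrite(path, img)
        mask = gk.load_lesion_mask(path, 12.0)
        assert mask.extent_mm == (6.0, 6.0)

    def test_area_is_pixel_count_times_pitch_squared(self):
        pix = np.zeros((50, 50), dtype=np.uint8)
        pix[10:20, 15:25] = 1  # 100 pixels
        mask = gk.LesionMask(pix, 12.0)
        assert mask.pixel_area_mm2 == pytest.approx(100 * 0.012**2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gk.LesionMask(np.zeros((4, 4, 3)), 12.0)
        with pytest.raises(ValueError):
            gk.LesionMask(np.zeros((4, 4)), 0.0)


class TestExtractMargins:
    def test_disk_perimeter_and_area(self):
        # radius 50 px = 0.6 mm at 12 um pitch
        m1, _ = gk.make_disk_pair((3, 3), 0.6, 0.0)
        contours = gk.extract_margins(m1)
        assert len(contours) == 1
        c = contours[0]
        assert c.closed and not c.is_hole
        assert c.perimeter_mm == pytest.approx(2 * np.pi * 0.6, rel=0.01)
        assert c.area_mm2 == pytest.approx(np.pi * 0.6**2, rel=0.01)

    def test_two_disks_get_distinct_components(self):
        masks = gk.rasterize_disks(
            [gk.Disk((1.5, 3.0), 0.4), gk.Disk((4.5, 3.0), 0.4)]
        )
        contours = gk.extract_margins(masks)
        assert len(contours) == 2
        assert len({c.component_id for c in contours}) == 2

    def test_hole_contour_detected_and_area_subtracted(self):
        pix = np.zeros((200, 200), dtype=np.uint8)
        pix[40:160, 40:160] = 1
        pix[80:120, 80:120] = 0  # hole
        mask = gk.LesionMask(pix, 12.0)
        contours = gk.extract_margins(mask)
        assert sorted(c.is_hole for c in contours) == [False, True]
        area = gk.lesion_area_mm2(contours)
        assert area == pytest.approx(mask.pixel_area_mm2, rel=0.02)

    def test_vertices_near_binary_boundary(self):
        m1, _ = gk.make_disk_pair((3, 3), 0.8, 0.0)
        c = gk.extract_margins(m1)[0]
        radii = np.hypot(c.vertices[:, 0] - 3, c.vertices[:, 1] - 3)
        assert np.all(np.abs(radii - 0.8) <= 0.5 * m1.pitch_mm)


class TestResampleMargin:
    def _circle_contour(self, radius, n=2000, center=(3.0, 3.0), perimeter=None):
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        xy = np.column_stack([radius * np.cos(t), radius * np.sin(t)])
        if perimeter is not None:
            # rescale so the polygon (not the ideal circle) has this perimeter
            closed = np.vstack([xy, xy[:1]])
            poly_perim = np.sum(np.hypot(*np.diff(closed, axis=0).T))
            xy *= perimeter / poly_perim
        xy += np.asarray(center)
        return MarginContour(vertices=xy, component_id=1)

    def test_point_count_is_floor_perimeter_over_spacing(self):
        # margin of perimeter 600 um sampled at 6 um -> 100 points
        radius = 0.6 / (2 * np.pi)
        contour = self._circle_contour(radius, perimeter=0.6)
        mask, _ = gk.make_disk_pair((3, 3), radius, 0.0)
        pts = gk.resample_margin(contour, mask, 6.0)
        assert len(pts) == 100

    def test_square_contour_points_and_normals(self):
        side = 0.6
        sq = np.array(
            [[2.7, 2.7], [3.3, 2.7], [3.3, 3.3], [2.7, 3.3]], dtype=float
        )
        contour = MarginContour(vertices=sq, component_id=1)
        pix = np.zeros((500, 500), dtype=np.uint8)
        pix[225:275, 225:275] = 1  # matching filled square
        mask = gk.LesionMask(pix, 12.0)
        pts = gk.resample_margin(contour, mask, side / 10 * 1000.0)
        assert len(pts) == 40
        # away from corners, normals are axis-aligned and outward
        from oracles import arclength_walk

        expected = arclength_walk(sq, side / 10)
        assert np.allclose(pts.points, expected[: len(pts)], atol=1e-9)
        mid = pts.points[1]  # on the bottom edge
        i = 1
        assert np.allclose(pts.normals[i], [0, -1], atol=1e-6)

    def test_spacing_reproduces_perimeter(self):
        m1, _ = gk.make_disk_pair((3, 3), 0.8, 0.0)
        c = gk.extract_margins(m1)[0]
        pts = gk.resample_margin(c, m1, 6.0)
        assert len(pts) * 0.006 == pytest.approx(c.perimeter_mm, abs=0.006)

    def test_normals_unit_and_outward(self):
        m1, _ = gk.make_disk_pair((3, 3), 0.8, 0.0)
        c = gk.extract_margins(m1)[0]
        pts = gk.resample_margin(c, m1, 6.0)
        assert np.allclose(np.hypot(*pts.normals.T), 1.0)
        radial = (pts.points - [3, 3]) / np.hypot(*(pts.points - [3, 3]).T)[:, None]
        assert np.all(np.einsum("ij,ij->i", pts.normals, radial) > 0.9)

    def test_too_small_contour_raises(self):
        c = self._circle_contour(0.0005)
        m1, _ = gk.make_disk_pair((3, 3), 0.1, 0.0)
        with pytest.raises(ValueError, match="too small"):
            gk.resample_margin(c, m1, 6000.0)


class TestFazCentroid:
    def test_regular_hexagon_centroid_is_center(self):
        t = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        hexagon = np.column_stack([3 + 0.3 * np.cos(t), 3 + 0.3 * np.sin(t)])
        assert np.allclose(gk.faz_centroid(hexagon), [3, 3], atol=1e-12)

    def test_triangle_closed_form(self):
        tri = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        assert np.allclose(gk.faz_centroid(tri), [1 / 3, 1 / 3])

    def test_degenerate_polygon_raises(self):
        with pytest.raises(ValueError):
            gk.faz_centroid(np.array([[0, 0], [1, 1], [2, 2]], dtype=float))


class TestFovealInvolvement:
    def test_lesion_over_fovea(self):
        m, _ = gk.make_disk_pair((3, 3), 1.0, 0.0)
        out = gk.classify_foveal_involvement(m, (3, 3))
        assert out == {"center_involved": True, "zone_involved": True}

    def test_far_lesion_spares_zone(self):
        m, _ = gk.make_disk_pair((5.0, 3.0), 0.5, 0.0)  # closest atrophy 1.5 mm
        out = gk.classify_foveal_involvement(m, (3, 3))
        assert out == {"center_involved": False, "zone_involved": False}

    def test_near_lesion_involves_zone_but_not_center(self):
        m, _ = gk.make_disk_pair((4.0, 3.0), 0.5, 0.0)  # closest atrophy 0.5 mm
        out = gk.classify_foveal_involvement(m, (3, 3))
        assert out == {"center_involved": False, "zone_involved": True}

    def test_monotone_in_zone_radius(self):
        m, _ = gk.make_disk_pair((4.0, 3.0), 0.5, 0.0)
        involved = [
            gk.classify_foveal_involvement(m, (3, 3), zone_radius_um=r)["zone_involved"]
            for r in (100, 300, 500, 700, 900, 1200)
        ]
        # once involved at some radius, involved at all larger radii
        assert involved == sorted(involved)

    def test_fovea_outside_raster_raises(self):
        m, _ = gk.make_disk_pair((3, 3), 0.5, 0.0)
        with pytest.raises(ValueError):
            gk.classify_foveal_involvement(m, (7.0, 3.0))


class TestGlobalRates:
    def test_gridsweep_style_effective_radius_rate(self):
        rates = gk.global_growth_rates(np.pi * 0.8**2, np.pi * 0.95**2, 1.0)
        assert rates.eff_radius_rate == pytest.approx(0.15)
        assert rates.area_rate == pytest.approx(np.pi * (0.9025 - 0.64))
        assert rates.sqrt_area_rate == pytest.approx(0.15 * np.sqrt(np.pi))

    def test_no_growth_gives_zero_rates(self):
        rates = gk.global_growth_rates(2.0, 2.0, 1.5)
        assert rates.area_rate == rates.sqrt_area_rate == rates.eff_radius_rate == 0.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        a1=st.floats(0.01, 30.0),
        a2=st.floats(0.01, 30.0),
        dt=st.floats(0.1, 5.0),
    )
    def test_sqrt_area_rate_is_sqrt_pi_times_radius_rate(self, a1, a2, dt):
        rates = gk.global_growth_rates(a1, a2, dt)
        if rates.eff_radius_rate != 0:
            assert rates.sqrt_area_rate / rates.eff_radius_rate == pytest.approx(
                np.sqrt(np.pi), rel=1e-12
            )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gk.global_growth_rates(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            gk.global_growth_rates(1.0, 2.0, 0.0)
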