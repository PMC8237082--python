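import numpy as np
import pytest

import gakinetics as gk
from gakinetics.comparators import DEFAULT_ZONES, disk_annulus_area
from gakinetics.synth import Disk
from oracles import exhaustive_nearest


FOVEA = (3.0, 3.0)


class TestZoneRates:
    def test_lesion_inside_zone_recovers_true_rate(self):
        d1, d2 = [Disk(FOVEA, 0.8)], [Disk(FOVEA, 0.95)]
        rates = gk.zone_effective_radius_rates(d1, d2, [(0.0, 1.0)], FOVEA, 1.0)
        assert rates[0] == pytest.approx(0.15)

    def test_saturated_zone_reports_zero(self):
        d1, d2 = [Disk(FOVEA, 1.5)], [Disk(FOVEA, 1.65)]
        rates = gk.zone_effective_radius_rates(d1, d2, [(0.0, 1.0)], FOVEA, 1.0)
        assert rates[0] == pytest.approx(0.0, abs=1e-12)

    def test_gridsweep_zone3_closed_form_at_r_alpha_2(self):
        scene = gk.make_two_circle_scene(2.0)
        rates = gk.zone_effective_radius_rates(
            scene.disks_v1, scene.disks_v2, DEFAULT_ZONES, scene.fovea_mm, 1.0
        )
        expected = np.sqrt(0.685) - 0.1  # A1 = 0.01*pi, A2 = 0.685*pi
        assert rates[2] == pytest.approx(expected, abs=1e-12)
        assert rates[2] / 0.15 == pytest.approx(4.851, abs=0.01)

    def test_raster_path_agrees_with_closed_form(self):
        scene = gk.make_two_circle_scene(1.4)
        m1, m2 = gk.SceneSpec(
            scene.disks_v1, scene.disks_v2, pixel_pitch_um=6.0
        ).to_masks()
        analytic = gk.zone_effective_radius_rates(
            scene.disks_v1, scene.disks_v2, DEFAULT_ZONES, scene.fovea_mm, 1.0
        )
        raster = gk.zone_effective_radius_rates(m1, m2, DEFAULT_ZONES, scene.fovea_mm, 1.0)
        # underlying zone areas agree within 0.5% -> rates within ~0.005
        assert np.allclose(raster, analytic, atol=0.005)

    def test_two_lesions_in_one_zone_underestimate_sum(self):
        # concavity of sqrt: zone rate < sum of individual rates
        d1 = [Disk((2.0, 3.0), 0.3), Disk((4.0, 3.0), 0.3)]
        d2 = [d.grown(0.15) for d in d1]
        zone = [(0.0, 2.5)]
        rate = gk.zone_effective_radius_rates(d1, d2, zone, FOVEA, 1.0)[0]
        assert rate < 0.3
        assert rate > 0.15  # but more than a single lesion's rate

    def test_circle_annulus_area_formula(self):
        # disk fully inside annulus
        assert disk_annulus_area(Disk((5.5, 3.0), 0.1), FOVEA, 2.0, 3.0) == pytest.approx(
            np.pi * 0.01
        )
        # concentric disk overlapping inner boundary
        assert disk_annulus_area(Disk(FOVEA, 2.15), FOVEA, 2.0, 3.0) == pytest.approx(
            np.pi * (2.15**2 - 4.0)
        )


class TestGridArtifactSweep:
    def test_zone3_peak_overestimation_exceeds_4_5(self):
        table = gk.sweep_grid_artifact()
        z3 = table[table.zone_id == 3]
        assert z3.ratio_to_true.max() > 4.5

    def test_isolated_lesion_fully_in_zone_has_ratio_one(self):
        d1, d2 = [Disk((5.5, 3.0), 0.1)], [Disk((5.5, 3.0), 0.25)]
        rate = gk.zone_effective_radius_rates(d1, d2, [(2.0, 3.0)], FOVEA, 1.0)[0]
        assert rate / 0.15 == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_at_sweep_end(self):
        table = gk.sweep_grid_artifact()
        z3 = table[(table.zone_id == 3) & np.isclose(table.R_alpha_mm, 2.1)]
        expected = np.sqrt(1.125) - np.sqrt(0.42)
        assert z3.rate_mm_per_yr.iloc[0] == pytest.approx(expected, abs=1e-12)


class TestDistanceComparator:
    def test_concentric_disks_radial_segments(self, disk_masks):
        m1, m2 = disk_masks
        trajs = gk.distance_based_trajectories(m1, m2)
        lengths = np.array([t.length_mm for t in trajs])
        assert np.median(lengths) == pytest.approx(0.15, abs=0.01)
        assert not any(t.crosses_nonatrophy for t in trajs)

    def test_identical_masks_zero_lengths(self, disk_masks):
        m1, _ = disk_masks
        trajs = gk.distance_based_trajectories(m1, m1)
        assert max(t.length_mm for t in trajs) <= 0.006

    def test_lengths_match_exhaustive_nearest_search(self, disk_masks):
        m1, m2 = disk_masks
        trajs = gk.distance_based_trajectories(m1, m2, spacing_um=60.0)
        from gakinetics.lesion import MarginPointSet, extract_margins, resample_margin

        pts1 = MarginPointSet.concatenate(
            [resample_margin(c, m1, 60.0) for c in extract_margins(m1)]
        ).points
        pts2 = MarginPointSet.concatenate(
            [resample_margin(c, m2, 60.0) for c in extract_margins(m2)]
        ).points
        dist, idx = exhaustive_nearest(pts2, pts1)
        assert len(trajs) == len(pts2)
        for t, d, i in zip(trajs, dist, idx):
            assert t.length_mm == pytest.approx(d, abs=1e-12)
            assert np.allclose(t.end_mm, pts1[i])

    def test_empty_visit1_margin_rejected(self):
        m1 = gk.LesionMask(np.zeros((100, 100), dtype=np.uint8), 12.0)
        m2, _ = gk.make_disk_pair((0.6, 0.6), 0.3, 0.0, eye_id="small")
        m2 = gk.LesionMask(m2.pixels[:100, :100], 12.0)
        with pytest.raises(ValueError):
            gk.distance_based_trajectories(m1, m2)


def _c_shape_scene():
    """Visit 1: a short arc blob; visit 2: a C grown around a spared core."""
    pitch = 0.012
    n = 500
    coords = (np.arange(n) + 0.5) * pitch
    gx, gy = np.meshgrid(coords, coords)
    rad = np.hypot(gx - 3.0, gy - 3.0)
    ang = np.degrees(np.arctan2(gy - 3.0, gx - 3.0))  # (-180, 180]
    annulus = (rad >= 0.35) & (rad <= 0.75)
    c_shape = annulus & ~((np.abs(ang - 90.0) < 25.0))
    blob = annulus & (np.abs(ang + 90.0) < 30.0)
    m1 = gk.LesionMask(blob.astype(np.uint8), 12.0, eye_id="cshape")
    m2 = gk.LesionMask(c_shape.astype(np.uint8), 12.0, eye_id="cshape")
    return m1, m2


class TestNonphysicalTrajectories:
    def test_distance_comparator_crosses_nonatrophy_but_model_does_not(self):
        m1, m2 = _c_shape_scene()
        dist_trajs = gk.distance_based_trajectories(m1, m2)
        assert any(t.crosses_nonatrophy for t in dist_trajs)
        res = gk.GrowthModel(m1, m2, (3.0, 3.0), 1.0,
                             params=gk.GrowthParams(grid_pitch_um=12.0)).fit()
        field = res.field
        for traj in res.trajectories:
            assert np.all(field.interp_phi2(traj.vertices) <= 0.5 * field.h_mm)
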