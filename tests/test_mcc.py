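"""MCC statistics: angles, polar order, velocity field, coverage, pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import GEOMETRY, make_set, make_track
from mucoflow import synthetic
from mucoflow.core import ChannelGeometry
from mucoflow.mcc import (
    MCCStats,
    alpha_shape_area,
    angle_histogram,
    area_avg_speed,
    compute_stats,
    mcc_coverage,
    polar_order,
    pool_sample,
    trajectory_angles,
    velocity_field,
)


def tracks_at_angles(angles_deg, length_um=30.0, geometry=GEOMETRY):
    """One straight 2-node track per requested angle from the inlet axis."""
    tracks = []
    for i, a in enumerate(np.atleast_1d(angles_deg)):
        d = synthetic._direction_unit(geometry.inlet_direction, float(a)) * length_um
        start = (600.0, 600.0)
        tracks.append(make_track(i, [start, (start[0] + d[0], start[1] + d[1])]))
    return make_set(tracks)


class TestAngles:
    def test_toward_inlet_is_zero_degrees(self, geometry):
        tset = make_set([make_track(0, [(100.0, 50.0), (60.0, 50.0)])])  # -x
        assert trajectory_angles(tset, geometry) == pytest.approx([0.0])

    def test_toward_outlet_is_180_degrees(self, geometry):
        tset = make_set([make_track(0, [(60.0, 50.0), (100.0, 50.0)])])  # +x
        assert abs(trajectory_angles(tset, geometry)[0]) == pytest.approx(180.0)

    def test_perpendicular_is_90_degrees(self, geometry):
        down = make_set([make_track(0, [(50.0, 10.0), (50.0, 60.0)])])
        up = make_set([make_track(0, [(50.0, 60.0), (50.0, 10.0)])])
        a_down = trajectory_angles(down, geometry)[0]
        a_up = trajectory_angles(up, geometry)[0]
        assert abs(a_down) == pytest.approx(90.0)
        assert abs(a_up) == pytest.approx(90.0)
        assert a_down == pytest.approx(-a_up)

    def test_zero_displacement_tracks_excluded(self, geometry):
        tset = make_set(
            [
                make_track(0, [(10.0, 10.0), (10.0, 10.0)]),
                make_track(1, [(50.0, 50.0), (20.0, 50.0)]),
            ]
        )
        assert len(trajectory_angles(tset, geometry)) == 1

    def test_generator_angle_convention_round_trips(self, geometry):
        for a in (0.0, 45.0, -120.0, 90.0, 180.0):
            got = trajectory_angles(tracks_at_angles([a]), geometry)[0]
            assert got == pytest.approx(a if a != -180 else 180.0, abs=1e-9)


class TestPolarOrder:
    def test_all_toward_inlet_gives_plus_one(self):
        assert polar_order(np.zeros(100)) == pytest.approx(1.0)

    def test_all_toward_outlet_gives_minus_one(self):
        assert polar_order(np.full(100, 180.0)) == pytest.approx(-1.0)

    def test_mixed_zero_and_ninety(self):
        assert polar_order(np.array([0.0, 90.0])) == pytest.approx(0.5)

    def test_uniform_angles_give_near_zero(self):
        rng = np.random.default_rng(42)
        angles = rng.uniform(-180.0, 180.0, 10_000)
        assert abs(polar_order(angles)) < 0.03  # ~2/sqrt(n) Monte-Carlo bound

    def test_perpendicular_flow_gives_exact_zero(self):
        angles = np.array([90.0, -90.0] * 50)
        assert polar_order(angles) == pytest.approx(0.0, abs=1e-12)

    def test_empty_set_undefined(self):
        with pytest.raises(ValueError):
            polar_order(np.array([]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-180.0, 180.0), min_size=1, max_size=50))
    def test_po_always_within_unit_interval(self, angles):
        assert -1.0 <= polar_order(np.array(angles)) <= 1.0

    def test_reversing_inlet_negates_po_exactly(self, geometry):
        rng = np.random.default_rng(3)
        tset = tracks_at_angles(rng.uniform(-180, 180, 64))
        po_fwd = polar_order(trajectory_angles(tset, geometry))
        po_rev = polar_order(trajectory_angles(tset, geometry.reversed()))
        assert po_rev == pytest.approx(-po_fwd, abs=1e-12)

    def test_recovers_generator_mean_direction_cosine(self, geometry):
        """Parameter recovery: PO of a directed scene with angular jitter
        matches the generator's mean-direction cosine within 2/sqrt(n)."""
        spec = synthetic.FlowSceneSpec(
            n_mcc=400, n_background=0, mcc_direction_deg=30.0,
            mcc_jitter_um=0.05, seed=17,
        )
        tracks, _ = synthetic.gen_bead_tracks(spec)
        po = polar_order(trajectory_angles(tracks, geometry))
        expected = np.cos(np.radians(30.0))
        assert po == pytest.approx(expected, abs=2 / np.sqrt(400))


class TestAngleHistogram:
    def test_single_direction_occupies_one_bin(self):
        counts, _ = angle_histogram(np.zeros(50), n_bins=36)
        assert counts.max() == 50 and (counts > 0).sum() == 1

    def test_counts_conserve_n(self):
        rng = np.random.default_rng(0)
        angles = rng.uniform(-180, 180, 777)
        counts, edges = angle_histogram(angles, n_bins=24)
        assert counts.sum() == 777
        assert len(counts) == 24 and len(edges) == 25

    def test_uniform_angles_fill_bins_multinomially(self):
        rng = np.random.default_rng(8)
        angles = rng.uniform(-180.0, 180.0, 36_000)
        counts, _ = angle_histogram(angles, n_bins=36)
        # each bin n*p = 1000 within 3 multinomial standard deviations
        sd = np.sqrt(36_000 * (1 / 36) * (35 / 36))
        assert np.all(np.abs(counts - 1000) <= 3.5 * sd)

    def test_boundary_angles_stay_in_domain(self):
        counts, _ = angle_histogram(np.array([180.0, -180.0]), n_bins=4)
        assert counts.sum() == 2

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            angle_histogram(np.zeros(3), n_bins=3)


class TestVelocityField:
    def test_constant_velocity_track_fills_cells_uniformly(self):
        # 1 um per frame at 30 fps -> (30, 0) um/s everywhere
        t = make_track(0, [(float(i), 35.0) for i in range(100)])
        field = velocity_field(make_set([t], field_size_um=(100.0, 100.0)), grid_um=10.0)
        active = field.active_mask
        assert active.sum() > 0
        np.testing.assert_allclose(field.u[active], 30.0)
        np.testing.assert_allclose(field.v[active], 0.0)

    def test_antiparallel_passes_average_to_zero_but_stay_active(self):
        fwd = make_track(0, [(float(i), 15.0) for i in range(30)])
        back = make_track(1, [(float(29 - i), 15.0) for i in range(30)])
        field = velocity_field(
            make_set([fwd, back], field_size_um=(30.0, 30.0)), grid_um=30.0
        )
        assert field.active_mask[0, 0]
        assert field.u[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_no_tracks_gives_empty_mask(self):
        field = velocity_field(make_set([], field_size_um=(50.0, 50.0)), grid_um=10.0)
        assert not field.active_mask.any()

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            velocity_field(make_set([], field_size_um=(50.0, 50.0)), grid_um=0.0)


class TestCoverage:
    def _field_from_mask(self, active, grid_um=20.0):
        from mucoflow.mcc import VelocityField

        u = np.where(active, 10.0, np.nan)
        v = np.where(active, 0.0, np.nan)
        return VelocityField(grid_um, u, v, active.astype(int))

    def test_fully_active_grid_covers_whole_field(self):
        active = np.ones((60, 60), bool)
        field = self._field_from_mask(active)
        geometry = ChannelGeometry(field_area_um2=(60 * 20.0) ** 2)
        assert mcc_coverage(field, geometry) == pytest.approx(1.0, abs=0.02)

    def test_empty_field_gives_zero(self):
        field = self._field_from_mask(np.zeros((10, 10), bool))
        assert mcc_coverage(field, ChannelGeometry(field_area_um2=4e4)) == 0.0

    def test_fewer_than_three_cells_give_zero_area(self):
        active = np.zeros((10, 10), bool)
        active[0, 0] = True
        field = self._field_from_mask(active)
        assert mcc_coverage(field, ChannelGeometry(field_area_um2=4e4)) == 0.0

    def test_half_field_band_covers_half(self):
        active = np.zeros((30, 30), bool)
        active[:15, :] = True
        field = self._field_from_mask(active)
        geometry = ChannelGeometry(field_area_um2=(30 * 20.0) ** 2)
        assert mcc_coverage(field, geometry) == pytest.approx(0.5, abs=0.05)

    def test_alpha_shape_agrees_with_grid_count_oracle(self):
        """On random dense activity, the alpha-shape area matches the
        brute-force active-cell count x cell area within 10%."""
        rng = np.random.default_rng(12)
        for trial in range(3):
            active = np.zeros((25, 25), bool)
            # a dense random blob: all cells within a random radius
            cy, cx = rng.uniform(8, 17, 2)
            r = rng.uniform(6, 10)
            yy, xx = np.mgrid[0:25, 0:25]
            active = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
            field = self._field_from_mask(active)
            geometry = ChannelGeometry(field_area_um2=(25 * 20.0) ** 2)
            cov = mcc_coverage(field, geometry, alpha_um=40.0)
            oracle = active.sum() * 20.0**2 / geometry.field_area_um2
            assert cov == pytest.approx(oracle, rel=0.10)

    def test_collinear_points_enclose_no_area(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0)])
        assert alpha_shape_area(pts, 10.0) == 0.0


class TestAreaAvgSpeed:
    def _uniform_field(self, active, speed):
        from mucoflow.mcc import VelocityField

        u = np.where(active, speed, np.nan)
        v = np.where(active, 0.0, np.nan)
        return VelocityField(20.0, u, v, active.astype(int))

    def test_full_coverage_returns_mean_speed(self):
        field = self._uniform_field(np.ones((10, 10), bool), 10.0)
        assert area_avg_speed(field, 1.0) == pytest.approx(10.0)

    def test_half_coverage_halves_speed(self):
        field = self._uniform_field(np.ones((10, 10), bool), 10.0)
        assert area_avg_speed(field, 0.5) == pytest.approx(5.0)

    def test_empty_field_gives_zero(self):
        field = self._uniform_field(np.zeros((10, 10), bool), 10.0)
        assert area_avg_speed(field, 0.0) == 0.0

    def test_never_exceeds_mean_active_speed(self, geometry):
        spec = synthetic.FlowSceneSpec(n_mcc=100, n_background=50, seed=6)
        tracks, _ = synthetic.gen_bead_tracks(spec)
        stats = compute_stats(tracks, geometry)
        assert stats.area_avg_speed_um_s <= stats.mean_active_speed_um_s + 1e-12


class TestPooling:
    def _stats(self, po, cov=0.5, m=5.0):
        return MCCStats(po, cov, m, 10.0, np.zeros(36, int),
                        np.linspace(-180, 180, 37), 10)

    def test_opposed_movies_pool_to_zero(self):
        pooled = pool_sample(
            [np.zeros(50), np.full(50, 180.0)],
            [self._stats(1.0), self._stats(-1.0)],
        )
        assert pooled.po == pytest.approx(0.0, abs=1e-12)
        assert pooled.n_trajectories == 100

    def test_single_movie_identity(self):
        angles = np.array([0.0, 45.0, -30.0])
        pooled = pool_sample([angles], [self._stats(polar_order(angles))])
        assert pooled.po == pytest.approx(polar_order(angles))
        assert pooled.n_trajectories == 3

    def test_field_metrics_weighted_by_area(self):
        pooled = pool_sample(
            [np.zeros(5), np.zeros(5)],
            [self._stats(1.0, cov=1.0, m=10.0), self._stats(1.0, cov=0.0, m=0.0)],
            field_areas_um2=[3.0, 1.0],
        )
        assert pooled.coverage == pytest.approx(0.75)
        assert pooled.area_avg_speed_um_s == pytest.approx(7.5)

    def test_no_movies_rejected(self):
        with pytest.raises(ValueError):
            pool_sample([], [])
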