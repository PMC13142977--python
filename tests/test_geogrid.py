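import numpy as np
import pytest

from hexdiv.geogrid import (EARTH_RADIUS_KM, GridIndex, GridSpec, build_grid,
                            great_circle_km, inverse_equal_earth,
                            jitter_points, project_equal_earth,
                            icosphere_points)


def test_icosphere_cell_count_closed_form():
    # 10 f^2 + 2 vertices for a class-I subdivision
    assert len(icosphere_points(1)) == 12
    assert len(icosphere_points(3)) == 92
    assert len(icosphere_points(7)) == 492


class TestGridGeometry:
    def test_main_grid_median_diameter_near_500km(self, main_grid):
        assert abs(main_grid.median_diameter_km - 500.0) <= 50.0

    def test_cells_tile_the_sphere(self, coarse_grid):
        total = sum(c.area_km2 for c in coarse_grid.cells)
        sphere = 4.0 * np.pi * EARTH_RADIUS_KM ** 2
        assert abs(total - sphere) / sphere < 1e-3

    def test_exactly_twelve_pentagons(self, coarse_grid):
        n_verts = np.array([len(c.boundary) for c in coarse_grid.cells])
        assert (n_verts == 5).sum() == 12
        assert set(n_verts) <= {5, 6}

    def test_unattainable_target_reports_closest(self):
        # between f=4 and f=5 there is no frequency within 10% of 2000 km
        with pytest.raises(ValueError, match="closest attainable"):
            build_grid(GridSpec(2000.0))

    def test_target_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(50.0)
        with pytest.raises(ValueError):
            GridSpec(5000.0)

    def test_determinism(self):
        g1 = build_grid(GridSpec(1500.0))
        g2 = build_grid(GridSpec(1500.0))
        assert [c.cell_id for c in g1.cells] == [c.cell_id for c in g2.cells]
        assert np.allclose([c.centroid_lon for c in g1.cells],
                           [c.centroid_lon for c in g2.cells])


class TestAssignment:
    def test_centroid_maps_to_own_cell(self, coarse_grid):
        lons = np.array([c.centroid_lon for c in coarse_grid.cells])
        lats = np.array([c.centroid_lat for c in coarse_grid.cells])
        ids = coarse_grid.assign_points(lons, lats)
        assert list(ids) == [c.cell_id for c in coarse_grid.cells]

    def test_total_coverage_antipodes(self, coarse_grid):
        lons = np.array([c.centroid_lon for c in coarse_grid.cells[:40]])
        lats = np.array([c.centroid_lat for c in coarse_grid.cells[:40]])
        anti_lon = (lons + 180.0 + 180.0) % 360.0 - 180.0
        ids = coarse_grid.assign_points(anti_lon, -lats)
        assert len(ids) == 40  # every antipode lands in some cell

    def test_invalid_coordinates_rejected_with_row(self, coarse_grid):
        with pytest.raises(ValueError, match=r"rows \[1\]"):
            coarse_grid.assign_points(np.array([0.0, 200.0]),
                                      np.array([0.0, 10.0]))

    def test_uniform_points_counts_match_areas(self, coarse_grid):
        # Monte-Carlo: per-cell counts of uniform sphere points are
        # consistent with cell areas (chi-square not absurdly large)
        rng = np.random.default_rng(0)
        n = 10_000
        z = rng.standard_normal((n, 3))
        z /= np.linalg.norm(z, axis=1, keepdims=True)
        lon = np.degrees(np.arctan2(z[:, 1], z[:, 0]))
        lat = np.degrees(np.arcsin(z[:, 2]))
        ids = coarse_grid.assign_points(lon, lat)
        counts = {c.cell_id: 0 for c in coarse_grid.cells}
        for i in ids:
            counts[i] += 1
        areas = np.array([c.area_km2 for c in coarse_grid.cells])
        expected = n * areas / areas.sum()
        observed = np.array([counts[c.cell_id] for c in coarse_grid.cells])
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        dof = coarse_grid.n_cells - 1
        # chi2 should be within ~5 sd of dof under uniformity
        assert chi2 < dof + 5.0 * np.sqrt(2.0 * dof)

    def test_csv_roundtrip_assignment(self, coarse_grid, tmp_path):
        path = tmp_path / "grid.csv"
        coarse_grid.to_csv(path)
        idx = GridIndex.from_csv(path)
        lons = np.array([c.centroid_lon for c in coarse_grid.cells[:20]])
        lats = np.array([c.centroid_lat for c in coarse_grid.cells[:20]])
        assert list(idx.assign_points(lons, lats)) == \
            [c.cell_id for c in coarse_grid.cells[:20]]


class TestJitter:
    def test_zero_radius_is_identity(self):
        lon, lat = jitter_points([10.0, 20.0], [0.0, 45.0], 0.0, seed=1)
        assert np.allclose(lon, [10.0, 20.0])
        assert np.allclose(lat, [0.0, 45.0])

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            jitter_points([0.0], [0.0], -1.0)

    def test_containment_at_250km(self):
        rng = np.random.default_rng(2)
        lon = rng.uniform(-180, 180, 2000)
        lat = rng.uniform(-85, 85, 2000)
        lon2, lat2 = jitter_points(lon, lat, 250.0, seed=9)
        d = great_circle_km(lon, lat, lon2, lat2)
        assert d.max() <= 250.0 + 1e-6

    def test_reproducible_for_fixed_seed(self):
        a = jitter_points([0.0] * 50, [0.0] * 50, 150.0, seed=4)
        b = jitter_points([0.0] * 50, [0.0] * 50, 150.0, seed=4)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_displacement_area_uniform(self):
        # distance CDF of an area-uniform draw on a spherical cap matches the
        # rejection-sampling oracle (KS test)
        from scipy import stats
        rng = np.random.default_rng(3)
        n = 4000
        radius = 800.0
        lon2, lat2 = jitter_points(np.zeros(n), np.zeros(n), radius, seed=5)
        d = great_circle_km(np.zeros(n), np.zeros(n), lon2, lat2)
        # oracle: rejection-sample uniform points in a planar-ish cap on the
        # sphere by drawing from the exact cap-area CDF inverse
        psi_max = radius / EARTH_RADIUS_KM
        u = rng.random(20000)
        psi_oracle = np.arccos(1.0 - u * (1.0 - np.cos(psi_max)))
        d_oracle = psi_oracle * EARTH_RADIUS_KM
        ks = stats.ks_2samp(d, d_oracle)
        assert ks.pvalue > 0.001


class TestEqualEarth:
    def test_natural_origin_maps_to_zero(self):
        x, y = project_equal_earth(150.0, 0.0)
        assert abs(float(x)) < 1e-9 and abs(float(y)) < 1e-9

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        lon = rng.uniform(-180, 180, 500)
        lat = rng.uniform(-89, 89, 500)
        x, y = project_equal_earth(lon, lat)
        lon2, lat2 = inverse_equal_earth(x, y)
        assert np.abs(lon2 - lon).max() < 1e-6
        assert np.abs(lat2 - lat).max() < 1e-6

    def test_equal_area_property(self):
        # small geodesic quadrilaterals anywhere on the globe project to
        # planar polygons whose area matches the spherical area within 0.5%
        rng = np.random.default_rng(7)
        step = 0.5  # degrees
        for _ in range(200):
            lon0 = rng.uniform(-170, 140)
            lat0 = rng.uniform(-80, 79)
            lons = np.array([lon0, lon0 + step, lon0 + step, lon0])
            lats = np.array([lat0, lat0, lat0 + step, lat0 + step])
            x, y = project_equal_earth(lons, lats)
            planar = 0.5 * abs(np.dot(x, np.roll(y, 1))
                               - np.dot(y, np.roll(x, 1)))
            spherical = (EARTH_RADIUS_KM ** 2 * np.radians(step)
                         * (np.sin(np.radians(lat0 + step))
                            - np.sin(np.radians(lat0))))
            assert abs(planar / spherical - 1.0) < 0.005
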