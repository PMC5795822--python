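"""Ground filtering, DSM/DTM/DVM construction and per-plant vigour classes,
each checked against brute-force reference implementations."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from vinesense.containers import GROUND, CANOPY, ElevationGrid, GeoTransform, PointCloud
from vinesense.errors import ValidationError
from vinesense.vigour import (
    ClassificationParams,
    VigourThresholds,
    ZonalParams,
    assign_vigour_class,
    classify_ground,
    classify_plants,
    compute_dvm,
    idw_interpolate,
    rasterize_dsm,
    rasterize_dtm,
    zonal_vigour,
)


# ---------------------------------------------------------------------------
# brute-force reference for the iterative ground filter: plain Python loops,
# per-point simplex lookup and explicit plane equations.


def _plane_check(verts, p, params):
    """Slope/vertical-distance acceptance against the plane of three points.

    Returns None when the three points are (near-)collinear.
    """
    cross = np.cross(verts[1] - verts[0], verts[2] - verts[0])
    if np.dot(cross, cross) < 1e-9 or abs(cross[2]) < 1e-12:
        return None
    a = np.column_stack([verts[:, 0], verts[:, 1], np.ones(3)])
    coef = np.linalg.solve(a, verts[:, 2])  # z = c0 x + c1 y + c2
    slope = np.degrees(np.arctan(np.hypot(coef[0], coef[1])))
    z_surf = coef[0] * p[0] + coef[1] * p[1] + coef[2]
    return abs(p[2] - z_surf) <= params.max_distance and slope <= params.max_angle


def brute_force_ground(xyz, params):
    n = len(xyz)
    # seed: lowest point per coarse cell (first wins on exact ties)
    cells = {}
    for i in range(n):
        key = (int(np.floor(xyz[i, 1] / params.grid_cell)),
               int(np.floor(xyz[i, 0] / params.grid_cell)))
        if key not in cells or xyz[i, 2] < xyz[cells[key], 2]:
            cells[key] = i
    is_ground = np.zeros(n, dtype=bool)
    is_ground[list(cells.values())] = True

    while True:
        ground_idx = np.flatnonzero(is_ground)
        tri = Delaunay(xyz[ground_idx, :2])
        added = []
        for i in np.flatnonzero(~is_ground):
            p = xyz[i]
            s = int(tri.find_simplex(p[:2]))
            if s >= 0:
                verts = xyz[ground_idx[tri.simplices[s]]]
                ok = _plane_check(verts, p, params)
                if ok:
                    added.append(i)
            else:
                dists = np.hypot(xyz[ground_idx, 0] - p[0], xyz[ground_idx, 1] - p[1])
                order = np.argsort(dists)
                verts = xyz[ground_idx[order[:3]]] if len(order) >= 3 else None
                ok = _plane_check(verts, p, params) if verts is not None else None
                if ok is None:
                    j = ground_idx[int(order[0])]
                    dz = abs(p[2] - xyz[j, 2])
                    dh = np.hypot(p[0] - xyz[j, 0], p[1] - xyz[j, 1])
                    ok = dz <= params.max_distance and np.degrees(
                        np.arctan2(dz, dh)
                    ) <= params.max_angle
                if ok:
                    added.append(i)
        if not added:
            break
        is_ground[added] = True
    return np.where(is_ground, GROUND, CANOPY).astype(np.uint8)


def _random_cloud(rng, n=300):
    """Undulating ground plus a few canopy blobs."""
    x = rng.uniform(0, 12, n)
    y = rng.uniform(0, 12, n)
    z = 0.3 * np.sin(x / 3) + 0.2 * np.cos(y / 4) + rng.normal(0, 0.03, n)
    blob = rng.random(n) < 0.25
    z[blob] += rng.uniform(0.8, 2.0, blob.sum())
    return PointCloud(np.column_stack([x, y, z]))


class TestClassifyGround:
    def test_flat_plane_with_blobs(self, rng):
        # random plane points plus a coarse grid so every seed cell sees ground
        gx, gy = np.meshgrid(np.linspace(0.5, 9.5, 10), np.linspace(0.5, 9.5, 10))
        plane = np.vstack([
            np.column_stack([rng.uniform(0, 10, 250), rng.uniform(0, 10, 250),
                             np.zeros(250)]),
            np.column_stack([gx.ravel(), gy.ravel(), np.zeros(100)]),
        ])
        centres = [(2, 2), (5, 7), (8, 4)]
        blobs = np.vstack([
            np.column_stack([cx + rng.uniform(-0.4, 0.4, 40),
                             cy + rng.uniform(-0.4, 0.4, 40),
                             np.full(40, 1.6)])
            for cx, cy in centres
        ])
        n_plane = len(plane)
        labelled = classify_ground(PointCloud(np.vstack([plane, blobs])))
        assert np.all(labelled.labels[:n_plane] == GROUND)
        assert np.all(labelled.labels[n_plane:] == CANOPY)

    def test_pure_terrain_has_no_canopy(self, rng):
        n = 200
        xyz = np.column_stack([rng.uniform(0, 8, n), rng.uniform(0, 8, n),
                               rng.normal(0, 0.02, n)])
        labelled = classify_ground(PointCloud(xyz))
        assert np.all(labelled.labels == GROUND)

    def test_steep_ramp_excluded_by_slope_limit(self, rng):
        """75-degree ramp with a 70-degree limit: no acceptance climbs the
        ramp — every point above the seed-minima surface stays canopy."""
        from scipy.interpolate import LinearNDInterpolator
        from vinesense.vigour import _seed_ground

        flat_x = rng.uniform(0, 5, 150)
        flat = np.column_stack([flat_x, rng.uniform(0, 5, 150), np.zeros(150)])
        ramp_x = rng.uniform(5, 7, 100)
        ramp = np.column_stack([ramp_x, rng.uniform(0, 5, 100),
                                (ramp_x - 5.0) * np.tan(np.radians(75))])
        cloud = PointCloud(np.vstack([flat, ramp]))
        params = ClassificationParams(max_distance=0.6, max_angle=70.0, grid_cell=1.0)
        labelled = classify_ground(cloud, params)

        seeds = _seed_ground(cloud, params.grid_cell)
        surface = LinearNDInterpolator(cloud.xyz[seeds, :2], cloud.z[seeds])
        ramp_indices = np.arange(150, 250)
        accepted = ramp_indices[labelled.labels[ramp_indices] == GROUND]
        dz = np.abs(cloud.z[accepted] - surface(cloud.xyz[accepted, :2]))
        # anything accepted hugs the seed surface; nothing above it creeps in
        assert np.all(np.isnan(dz) | (dz <= 0.05))
        above = ramp_indices[
            cloud.z[ramp_indices] - surface(cloud.xyz[ramp_indices, :2]) > 0.6
        ]
        assert np.all(labelled.labels[above] == CANOPY)

    def test_matches_brute_force_on_random_clouds(self):
        params = ClassificationParams(grid_cell=2.0)
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            cloud = _random_cloud(rng, n=int(rng.integers(100, 500)))
            got = classify_ground(cloud, params).labels
            expected = brute_force_ground(cloud.xyz, params)
            np.testing.assert_array_equal(got, expected)

    def test_idempotent_on_labelled_cloud(self, rng):
        cloud = _random_cloud(rng)
        once = classify_ground(cloud)
        twice = classify_ground(once)
        np.testing.assert_array_equal(once.labels, twice.labels)

    def test_vertical_column_is_degenerate(self):
        xyz = np.column_stack([np.full(10, 1.0), np.full(10, 2.0),
                               np.linspace(0, 5, 10)])
        with pytest.raises(ValidationError, match="degenerate"):
            classify_ground(PointCloud(xyz))


class TestRasters:
    def test_dsm_single_point_per_cell(self):
        xyz = np.array([[0.5, 0.5, 3.0], [1.5, 0.5, 4.0]])
        dsm = rasterize_dsm(PointCloud(xyz), cell=1.0)
        r, c = dsm.transform.index_of(0.5, 0.5)
        assert dsm.values[r, c] == 3.0

    def test_dsm_takes_cell_maximum(self):
        xyz = np.array([[0.5, 0.5, 1.0], [0.6, 0.4, 1.6]])
        dsm = rasterize_dsm(PointCloud(xyz), cell=1.0)
        assert np.nanmax(dsm.values) == 1.6

    def test_dsm_matches_exhaustive_cell_max(self, rng):
        cloud = PointCloud(np.column_stack([rng.uniform(0, 5, 400),
                                            rng.uniform(0, 5, 400),
                                            rng.normal(2, 1, 400)]))
        dsm = rasterize_dsm(cloud, cell=0.5)
        rows, cols = dsm.transform.index_of(cloud.x, cloud.y)
        for r in range(dsm.shape[0]):
            for c in range(dsm.shape[1]):
                here = (rows == r) & (cols == c)
                if here.any():
                    assert dsm.values[r, c] == cloud.z[here].max()
                else:
                    assert np.isnan(dsm.values[r, c])

    def test_dtm_flat_ground_is_constant(self, rng):
        xyz = np.column_stack([rng.uniform(0, 5, 500), rng.uniform(0, 5, 500),
                               np.full(500, 5.0)])
        dtm = rasterize_dtm(PointCloud(xyz), cell=0.5)
        np.testing.assert_allclose(dtm.values, 5.0)

    def test_dtm_fills_hole_under_vine(self, rng):
        x = rng.uniform(0, 6, 3000)
        y = rng.uniform(0, 6, 3000)
        hole = (np.abs(x - 3) < 0.5) & (np.abs(y - 3) < 0.5)
        cloud = PointCloud(np.column_stack([x[~hole], y[~hole],
                                            np.full((~hole).sum(), 5.0)]))
        dtm = rasterize_dtm(cloud, cell=0.25)
        r, c = dtm.transform.index_of(3.0, 3.0)
        assert dtm.values[r, c] == pytest.approx(5.0, abs=1e-6)
        assert np.isfinite(dtm.values).all()

    def test_dtm_recovers_tilted_plane_in_holes(self, rng):
        x = rng.uniform(0, 6, 6000)
        y = rng.uniform(0, 6, 6000)
        hole = (np.abs(x - 3) < 0.5) & (np.abs(y - 2) < 0.4)
        z = 10.0 + 0.1 * x - 0.05 * y
        cloud = PointCloud(np.column_stack([x[~hole], y[~hole], z[~hole]]))
        dtm = rasterize_dtm(cloud, cell=0.2)
        rr, cc = np.mgrid[0 : dtm.shape[0], 0 : dtm.shape[1]]
        cx, cy = dtm.transform.cell_center(rr, cc)
        in_hole = (np.abs(cx - 3) < 0.4) & (np.abs(cy - 2) < 0.3)
        expected = 10.0 + 0.1 * cx[in_hole] - 0.05 * cy[in_hole]
        assert np.abs(dtm.values[in_hole] - expected).max() < 0.02

    def test_dtm_needs_three_points(self):
        with pytest.raises(ValidationError, match="3 ground points"):
            rasterize_dtm(PointCloud(np.array([[0, 0, 1.0], [1, 1, 1.0]])), cell=1.0)

    def test_dvm_zero_when_dsm_equals_dtm(self, rng):
        t = GeoTransform(0, 10, 1.0)
        values = rng.uniform(0, 5, (10, 10))
        dvm = compute_dvm(ElevationGrid(values, t, "DSM"),
                          ElevationGrid(values.copy(), t, "DTM"))
        np.testing.assert_array_equal(dvm.values, 0.0)

    def test_dvm_clips_negatives_and_keeps_nodata(self):
        t = GeoTransform(0, 2, 1.0)
        dsm = ElevationGrid(np.array([[1.0, np.nan], [0.2, 3.0]]), t, "DSM")
        dtm = ElevationGrid(np.array([[1.5, 1.0], [0.1, 1.0]]), t, "DTM")
        dvm = compute_dvm(dsm, dtm)
        assert dvm.values[0, 0] == 0.0  # clipped
        assert np.isnan(dvm.values[0, 1])
        assert dvm.values[1, 1] == 2.0

    def test_dvm_grid_mismatch_rejected(self):
        a = ElevationGrid(np.zeros((2, 2)), GeoTransform(0, 2, 1.0), "DSM")
        b = ElevationGrid(np.zeros((3, 3)), GeoTransform(0, 3, 1.0), "DTM")
        with pytest.raises(ValidationError):
            compute_dvm(a, b)


class TestZonal:
    class _Plant:
        def __init__(self, tree_number, x, y):
            self.tree_number, self.x, self.y = tree_number, x, y

    def test_constant_dvm_stats(self):
        dvm = ElevationGrid(np.full((20, 20), 1.3), GeoTransform(0, 1.0, 0.05), "DVM")
        out = zonal_vigour(dvm, [self._Plant(1, 0.5, 0.5)])
        assert out.loc[1, "max"] == 1.3
        assert out.loc[1, "mean"] == pytest.approx(1.3)
        assert out.loc[1, "count"] > 0

    def test_tiny_radius_at_cell_centre_counts_one(self):
        dvm = ElevationGrid(np.arange(16.0).reshape(4, 4),
                            GeoTransform(0, 4.0, 1.0), "DVM")
        out = zonal_vigour(dvm, [self._Plant(1, 1.5, 2.5)],
                           ZonalParams(radius=0.4))
        assert out.loc[1, "count"] == 1
        assert out.loc[1, "max"] == dvm.values[1, 1]

    def test_matches_exhaustive_distance_filter(self, rng):
        dvm = ElevationGrid(rng.uniform(0, 2, (30, 30)),
                            GeoTransform(0, 1.5, 0.05), "DVM")
        plants = [self._Plant(i + 1, rng.uniform(0.2, 1.3), rng.uniform(0.2, 1.3))
                  for i in range(10)]
        out = zonal_vigour(dvm, plants, ZonalParams(radius=0.2))
        rr, cc = np.mgrid[0:30, 0:30]
        cx, cy = dvm.transform.cell_center(rr, cc)
        for p in plants:
            inside = (cx - p.x) ** 2 + (cy - p.y) ** 2 <= 0.2**2
            vals = dvm.values[inside]
            assert out.loc[p.tree_number, "max"] == vals.max()
            assert out.loc[p.tree_number, "mean"] == pytest.approx(vals.mean())
            assert out.loc[p.tree_number, "count"] == inside.sum()

    def test_out_of_reach_trunk_warns_and_misses(self, caplog):
        dvm = ElevationGrid(np.full((4, 4), 1.0), GeoTransform(0, 4.0, 1.0), "DVM")
        with caplog.at_level("WARNING"):
            out = zonal_vigour(dvm, [self._Plant(1, 50.0, 50.0)])
        assert out.loc[1, "count"] == 0
        assert np.isnan(out.loc[1, "max"])
        assert "no DVM cells" in caplog.text


class TestClasses:
    @pytest.mark.parametrize(
        "height,expected",
        [(1.8, 5), (1.75, 5), (1.6, 4), (1.3, 3), (0.8, 2), (0.05, 1), (0.0, 1)],
    )
    def test_wire_rule(self, height, expected):
        assert assign_vigour_class(height) == expected

    def test_vectorised_matches_scalar(self, rng):
        heights = rng.uniform(0, 2.2, 100)
        vec = assign_vigour_class(heights)
        for h, c in zip(heights, vec):
            assert assign_vigour_class(float(h)) == c

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            VigourThresholds(bottom_wire=1.6, middle_wire=1.5)

    def test_no_canopy_cells_forces_class_one(self):
        import pandas as pd
        zonal = pd.DataFrame({"max": [np.nan, 1.8], "mean": [np.nan, 1.7],
                              "count": [0, 12]}, index=[1, 2])
        cls = classify_plants(zonal)
        assert cls.loc[1] == 1
        assert cls.loc[2] == 5


class TestIdw:
    def test_single_sample_constant_inside_radius(self):
        grid = (GeoTransform(0, 4, 1.0), (4, 4))
        out = idw_interpolate(np.array([[2.0, 2.0]]), np.array([3.0]), grid,
                              max_radius=10.0)
        np.testing.assert_allclose(out.values, 3.0)

    def test_exact_at_coincident_sample(self):
        grid = (GeoTransform(0, 4, 1.0), (4, 4))
        out = idw_interpolate(np.array([[1.5, 2.5], [3.0, 3.0]]),
                              np.array([7.0, 1.0]), grid)
        r, c = grid[0].index_of(1.5, 2.5)
        assert out.values[r, c] == 7.0

    def test_midpoint_of_two_samples_is_mean(self):
        grid = (GeoTransform(0, 0.75, 0.5), (1, 5))
        out = idw_interpolate(np.array([[0.25, 0.5], [2.25, 0.5]]),
                              np.array([2.0, 4.0]), grid)
        r, c = grid[0].index_of(1.25, 0.5)
        assert out.values[r, c] == pytest.approx(3.0)

    def test_bounded_by_sample_range(self, rng):
        grid = (GeoTransform(0, 10, 0.5), (20, 20))
        xy = rng.uniform(0, 10, (15, 2))
        v = rng.uniform(1, 5, 15)
        out = idw_interpolate(xy, v, grid)
        assert np.nanmin(out.values) >= v.min() - 1e-9
        assert np.nanmax(out.values) <= v.max() + 1e-9
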