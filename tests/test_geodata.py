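"""Grid conventions, geodesic distance, map algebra and I/O round-trips."""

import json

import numpy as np
import pandas as pd
import pytest

import envenomap as em
from envenomap.geodata import (
    EnvStack,
    GridMismatchError,
    PointSet,
    Raster,
    haversine_km,
    read_env_stack,
    read_occurrences,
    read_points,
    write_env_stack,
    write_points,
    write_raster,
    read_raster,
)


class TestHaversine:
    def test_identity_is_zero(self):
        assert haversine_km(0, 0, 0, 0) == 0.0

    def test_one_degree_at_equator(self):
        # closed form: pi/180 * 6371 km
        assert haversine_km(0, 0, 1, 0) == pytest.approx(np.pi / 180 * 6371.0, abs=1e-6)

    def test_symmetry_random_pairs(self):
        rng = np.random.default_rng(0)
        lon = rng.uniform(-180, 180, (100, 2))
        lat = rng.uniform(-90, 90, (100, 2))
        d_pq = haversine_km(lon[:, 0], lat[:, 0], lon[:, 1], lat[:, 1])
        d_qp = haversine_km(lon[:, 1], lat[:, 1], lon[:, 0], lat[:, 0])
        np.testing.assert_allclose(d_pq, d_qp, rtol=0, atol=1e-12)
        assert (d_pq >= 0).all()

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            haversine_km(np.nan, 0, 1, 1)


class TestRasterizePoints:
    def test_cell_center_maps_to_its_cell(self):
        grid = em.GridSpec(4, 5, 10.0, 50.0, 0.5)
        for r in range(4):
            for c in range(5):
                x, y = grid.cell_center(r, c)
                pts = PointSet([0], [x], [y])
                cells, rejects = em.rasterize_points_to_cells(pts, grid)
                assert cells == [(r, c)] and rejects == []

    def test_edge_points_follow_half_open_intervals(self):
        # brute-force interval arithmetic on a 3x3 grid
        grid = em.GridSpec(3, 3, 0.0, 3.0, 1.0)
        xs = [0.0, 1.0, 1.5, 2.0, 2.9999]
        ys = [3.0, 2.0, 1.5, 1.0, 0.0001]
        for x in xs:
            for y in ys:
                cells, _ = em.rasterize_points_to_cells(PointSet([0], [x], [y]), grid)
                (r, c) = cells[0]
                # expected cell by direct interval check [edge, edge+1)
                c_exp = next(j for j in range(3) if j <= x < j + 1)
                r_exp = next(i for i in range(3) if 3 - i >= y > 3 - i - 1)
                assert (r, c) == (r_exp, c_exp)

    def test_out_of_extent_point_goes_to_rejects(self):
        grid = em.GridSpec(3, 3, 0.0, 3.0, 1.0)
        pts = PointSet([0, 1], [1.5, 99.0], [1.5, 1.5], crs_tag="EPSG:4326")
        cells, rejects = em.rasterize_points_to_cells(pts, grid)
        assert cells == [(1, 1)]
        assert rejects == [1]

    def test_empty_pointset(self):
        grid = em.GridSpec(3, 3, 0.0, 3.0, 1.0)
        pts = PointSet([], np.array([]), np.array([]))
        assert em.rasterize_points_to_cells(pts, grid) == ([], [])


class TestDistanceRaster:
    def test_city_at_cell_center_gives_zero(self):
        grid = em.GridSpec(5, 5, 0.0, 5.0, 1.0, "planar")
        x, y = grid.cell_center(2, 3)
        d = em.distance_to_points_raster(grid, PointSet(["c"], [x], [y], "planar"))
        assert d.values[2, 3] == 0.0

    @pytest.mark.parametrize("crs", ["planar", "EPSG:4326"])
    def test_matches_bruteforce_nearest_point(self, crs):
        grid = em.GridSpec(5, 5, 10.0, 40.0, 0.2, crs)
        rng = np.random.default_rng(3)
        cities = PointSet(
            ["a", "b"], 10.0 + rng.uniform(0, 1, 2), 39.0 + rng.uniform(0, 1, 2), crs
        )
        d = em.distance_to_points_raster(grid, cities)
        from envenomap.geodata import point_distance

        for r in range(5):
            for c in range(5):
                x, y = grid.cell_center(r, c)
                expected = min(
                    point_distance(x, y, cx, cy, crs) for cx, cy in zip(cities.x, cities.y)
                )
                assert d.values[r, c] == pytest.approx(expected, abs=1e-12)

    def test_adding_a_city_never_increases_distance(self):
        grid = em.GridSpec(6, 6, 0.0, 6.0, 1.0, "planar")
        rng = np.random.default_rng(4)
        xs, ys = rng.uniform(0, 6, 4), rng.uniform(0, 6, 4)
        d3 = em.distance_to_points_raster(grid, PointSet(list("abc"), xs[:3], ys[:3], "planar"))
        d4 = em.distance_to_points_raster(grid, PointSet(list("abcd"), xs, ys, "planar"))
        assert (d4.values <= d3.values + 1e-12).all()

    def test_empty_city_set_rejected(self):
        grid = em.GridSpec(3, 3, 0.0, 3.0, 1.0, "planar")
        with pytest.raises(ValueError, match="no healthcare locations"):
            em.distance_to_points_raster(grid, PointSet([], np.array([]), np.array([]), "planar"))


class TestMapAlgebra:
    def test_masked_cells_propagate_through_product_and_sum(self):
        grid = em.GridSpec(3, 3, 0.0, 3.0, 1.0)
        a = Raster(grid, np.ones((3, 3)), np.zeros((3, 3), bool))
        mask_b = np.zeros((3, 3), bool)
        mask_b[0, 0] = True
        b = Raster(grid, np.full((3, 3), 2.0), mask_b)
        for out in (a * b, a + b, b.threshold(1.0)):
            assert out.mask[0, 0]
            assert not out.mask[1:, :].any()
            assert np.isnan(out.values[0, 0])

    def test_grid_mismatch_raises(self):
        a = Raster(em.GridSpec(3, 3, 0.0, 3.0, 1.0), np.ones((3, 3)))
        b = Raster(em.GridSpec(3, 3, 1.0, 3.0, 1.0), np.ones((3, 3)))
        with pytest.raises(GridMismatchError):
            a * b


class TestIO:
    def test_single_band_roundtrip_bit_exact(self, tmp_path):
        grid = em.GridSpec(10, 10, 47.5, 31.0, 0.01)
        rng = np.random.default_rng(1)
        vals = rng.random((10, 10)).astype(np.float32).astype(float)
        mask = rng.random((10, 10)) < 0.2
        r = Raster(grid, np.where(mask, np.nan, vals), mask)
        path = tmp_path / "r.tif"
        write_raster(path, r)
        back = read_raster(path)
        assert back.grid == grid
        np.testing.assert_array_equal(back.mask, r.mask)
        np.testing.assert_array_equal(back.values[~mask], r.values[~mask])

    def test_multiband_stack_preserves_layer_order_and_names(self, tmp_path):
        grid = em.GridSpec(6, 7, 0.0, 6.0, 1.0)
        rng = np.random.default_rng(2)
        names = ["gdd", "bio4", "bio12", "bio15", "topo_het"]
        layers = {
            n: Raster(grid, rng.random((6, 7)).astype(np.float32).astype(float))
            for n in names
        }
        path = tmp_path / "stack.tif"
        write_env_stack(path, EnvStack(grid, layers))
        back = read_env_stack(path)
        assert back.layer_names == names
        for n in names:
            np.testing.assert_array_equal(back.layers[n].values, layers[n].values)

    def test_occurrence_csv_missing_lat_column(self, tmp_path):
        p = tmp_path / "occ.csv"
        pd.DataFrame({"species": ["a"], "lon": [1.0]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="lat"):
            read_occurrences(p)

    def test_city_points_csv_and_geojson(self, tmp_path):
        csv = tmp_path / "cities.csv"
        pts = PointSet(["x", "y"], np.array([48.1, 48.2]), np.array([31.1, 31.2]))
        write_points(csv, pts)
        back = read_points(csv)
        np.testing.assert_allclose(back.x, pts.x)
        gj = tmp_path / "cities.geojson"
        gj.write_text(
            json.dumps(
                {
                    "type": "FeatureCollection",
                    "features": [
                        {
                            "type": "Feature",
                            "geometry": {"type": "Point", "coordinates": [48.3, 31.3]},
                            "properties": {"name": "z"},
                        }
                    ],
                }
            )
        )
        back2 = read_points(gj)
        assert back2.ids == ["z"] and back2.x[0] == 48.3
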