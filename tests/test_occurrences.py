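"""Thinning, pseudo-absence and training-table protocol guarantees."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import envenomap as em
from envenomap.geodata import PointSet, pairwise_distances


def _occ(lons, lats, species="sp"):
    return em.OccurrenceSet(species, PointSet(list(range(len(lons))), lons, lats))


class TestThinning:
    def test_single_point_unchanged(self):
        occ = em.thin_occurrences(_occ([48.0], [31.0]), 1.0, seed=0)
        assert len(occ) == 1 and occ.thinned

    def test_two_close_points_keep_exactly_one(self):
        # ~0.5 km apart at 31N (0.0052 degrees of latitude)
        occ = em.thin_occurrences(_occ([48.0, 48.0], [31.0, 31.0045]), 1.0, seed=0)
        assert len(occ) == 1

    def test_two_km_lattice_all_retained(self):
        lats = 31.0 + np.arange(5) * (2.0 / 111.195)
        lons = np.full(5, 48.0)
        occ = em.thin_occurrences(_occ(lons, lats), 1.0, seed=1)
        assert len(occ) == 5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_output_satisfies_pairwise_oracle_and_maximality(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        pts = PointSet(list(range(n)), 48 + rng.uniform(0, 0.05, n), 31 + rng.uniform(0, 0.05, n))
        occ = em.OccurrenceSet("sp", pts)
        thinned = em.thin_occurrences(occ, 1.0, seed=seed)
        D_kept = pairwise_distances(thinned.points)
        n_kept = len(thinned.points)
        off = D_kept[~np.eye(n_kept, dtype=bool)]
        assert (off >= 1.0).all()
        # maximality: every original point is within 1 km of a kept point
        D_all = em.geodata.point_distance(
            pts.x[:, None], pts.y[:, None],
            thinned.points.x[None, :], thinned.points.y[None, :],
        )
        assert (D_all.min(axis=1) < 1.0 + 1e-9).all()

    def test_idempotence(self):
        rng = np.random.default_rng(9)
        n = 60
        occ = _occ(48 + rng.uniform(0, 0.05, n), 31 + rng.uniform(0, 0.05, n))
        once = em.thin_occurrences(occ, 1.0, seed=4)
        twice = em.thin_occurrences(once, 1.0, seed=99)
        np.testing.assert_array_equal(np.sort(once.points.x), np.sort(twice.points.x))


class TestOccupiedEcoregions:
    def test_labels_match_exhaustive_cell_lookup(self, landscape):
        rng = np.random.default_rng(11)
        grid = landscape.ecoregions.grid
        rows = rng.integers(0, grid.n_rows, 30)
        cols = rng.integers(0, grid.n_cols, 30)
        xs = grid.x_origin + (cols + 0.5) * grid.cell_size
        ys = grid.y_origin - (rows + 0.5) * grid.cell_size
        occ = _occ(xs, ys)
        expected = {int(landscape.ecoregions.values[r, c]) for r, c in zip(rows, cols)}
        assert em.occupied_ecoregions(occ, landscape.ecoregions) == expected

    def test_empty_set_rejected(self, landscape):
        occ = em.OccurrenceSet("sp", PointSet([], np.array([]), np.array([])))
        with pytest.raises(ValueError):
            em.occupied_ecoregions(occ, landscape.ecoregions)


class TestPseudoAbsences:
    def test_default_background_size_is_5000(self):
        # needs a grid with enough candidate cells
        import envenomap.synthetic as syn
        grid = em.GridSpec(100, 100, 48.0, 32.0, 1.0 / 120.0)
        eco = syn.simulate_ecoregions(grid, n_regions=2, seed=1)
        occ = _occ([48.4], [31.6])
        labels = em.occupied_ecoregions(occ, eco)
        bg = em.generate_pseudo_absences(eco, labels, occ)
        assert bg.n_requested == 5000
        assert len(bg.points) == 5000

    def test_membership_constraints_hold_exhaustively(self, landscape):
        rng = np.random.default_rng(13)
        grid = landscape.ecoregions.grid
        xs = grid.x_origin + rng.uniform(0, grid.n_cols * grid.cell_size, 20)
        ys = grid.y_origin - rng.uniform(0, grid.n_rows * grid.cell_size, 20)
        occ = _occ(xs, ys)
        labels = em.occupied_ecoregions(occ, landscape.ecoregions)
        bg = em.generate_pseudo_absences(landscape.ecoregions, labels, occ, n=500, seed=2)
        bg_cells, rejects = em.rasterize_points_to_cells(bg.points, grid)
        assert rejects == []
        presence_cells = set(em.rasterize_points_to_cells(occ.points, grid)[0])
        for r, c in bg_cells:
            assert int(landscape.ecoregions.values[r, c]) in labels
            assert (r, c) not in presence_cells

    def test_shortfall_uses_all_candidates_with_warning(self, landscape, caplog):
        occ = _occ([landscape.env.grid.x_origin + 0.01], [landscape.env.grid.y_origin - 0.01])
        labels = em.occupied_ecoregions(occ, landscape.ecoregions)
        with caplog.at_level("WARNING"):
            bg = em.generate_pseudo_absences(landscape.ecoregions, labels, occ, n=10**6, seed=3)
        assert len(bg.points) < 10**6
        assert any("candidate cells" in r.message for r in caplog.records)

    def test_deterministic_given_seed(self, landscape):
        occ = _occ([48.2], [31.7])
        labels = em.occupied_ecoregions(occ, landscape.ecoregions)
        a = em.generate_pseudo_absences(landscape.ecoregions, labels, occ, n=100, seed=7)
        b = em.generate_pseudo_absences(landscape.ecoregions, labels, occ, n=100, seed=7)
        np.testing.assert_array_equal(a.points.x, b.points.x)


class TestTrainingTable:
    def test_absence_weight_closed_form(self, landscape, species_truth):
        import envenomap.synthetic as syn
        pts = syn.sample_occurrences(species_truth, n=130, seed=31)
        occ = em.OccurrenceSet("v", pts)
        labels = em.occupied_ecoregions(occ, landscape.ecoregions)
        bg = em.generate_pseudo_absences(landscape.ecoregions, labels, occ, n=900, seed=32)
        tbl = em.assemble_training_table(occ, bg, landscape.env)
        n_p = int((tbl.df.response == 1).sum())
        n_a = int((tbl.df.response == 0).sum())
        w_abs = tbl.df.loc[tbl.df.response == 0, "weight"].unique()
        assert len(w_abs) == 1
        assert w_abs[0] == pytest.approx(n_p / n_a, rel=1e-12)
        assert tbl.weighted_prevalence == pytest.approx(0.5, abs=1e-12)

    def test_equal_counts_give_unit_weights(self):
        df = pd.DataFrame(
            {
                "response": [1, 1, 0, 0],
                "weight": np.nan,
                "lon": [0.1, 0.2, 0.3, 0.4],
                "lat": [0.1, 0.2, 0.3, 0.4],
            }
        )
        # build via assemble on a tiny planar landscape
        grid = em.GridSpec(4, 4, 0.0, 4.0, 1.0, "planar")
        vals = np.arange(16.0).reshape(4, 4)
        env = em.EnvStack(grid, {"L": em.Raster(grid, vals)})
        occ = em.OccurrenceSet("s", PointSet([0, 1], [0.5, 1.5], [0.5, 0.5], "planar"))
        bg = em.BackgroundSet("s", PointSet([0, 1], [2.5, 3.5], [0.5, 0.5], "planar"), 2, frozenset(), 0)
        tbl = em.assemble_training_table(occ, bg, env)
        assert (tbl.df.weight == 1.0).all()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(n_p=st.integers(1, 400), n_a=st.integers(1, 400))
    def test_weighted_prevalence_is_half_for_any_class_sizes(self, n_p, n_a):
        w = np.r_[np.ones(n_p), np.full(n_a, n_p / n_a)]
        y = np.r_[np.ones(n_p), np.zeros(n_a)]
        assert (w * y).sum() / w.sum() == pytest.approx(0.5, abs=1e-12)

    def test_masked_predictor_rows_dropped_and_counted(self):
        grid = em.GridSpec(2, 2, 0.0, 2.0, 1.0, "planar")
        vals = np.array([[1.0, np.nan], [2.0, 3.0]])
        env = em.EnvStack(grid, {"L": em.Raster(grid, vals)})
        occ = em.OccurrenceSet("s", PointSet([0, 1], [0.5, 1.5], [1.5, 1.5], "planar"))
        bg = em.BackgroundSet("s", PointSet([0, 1], [0.5, 1.5], [0.5, 0.5], "planar"), 2, frozenset(), 0)
        tbl = em.assemble_training_table(occ, bg, env)
        assert tbl.n_dropped == 1
        assert len(tbl.df) == 3

    def test_single_class_after_drops_rejected(self):
        grid = em.GridSpec(1, 2, 0.0, 1.0, 1.0, "planar")
        env = em.EnvStack(grid, {"L": em.Raster(grid, np.array([[np.nan, 1.0]]))})
        occ = em.OccurrenceSet("s", PointSet([0], [0.5], [0.5], "planar"))
        bg = em.BackgroundSet("s", PointSet([0], [1.5], [0.5], "planar"), 1, frozenset(), 0)
        with pytest.raises(ValueError, match="both classes"):
            em.assemble_training_table(occ, bg, env)
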