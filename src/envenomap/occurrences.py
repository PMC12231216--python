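"""Presence thinning, ecoregion-constrained pseudo-absences, training tables.

The modelling protocol contrasts presences against background
(pseudo-absence) points drawn only from the ecoregions where the species
was actually recorded, and re-weights absences so the weighted prevalence
of the training data is exactly 0.5 regardless of the presence/background
imbalance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geodata import (
    EnvStack,
    PointSet,
    Raster,
    pairwise_distances,
    rasterize_points_to_cells,
)

logger = logging.getLogger(__name__)


@dataclass
class OccurrenceSet:
    """Presence points of one species, optionally spatially thinned."""

    species: str
    points: PointSet
    thinned: bool = False
    min_dist_km: float | None = None

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class BackgroundSet:
    """Pseudo-absence points constrained to the species' occupied ecoregions."""

    species: str
    points: PointSet
    n_requested: int
    ecoregion_labels_used: frozenset
    seed: int


@dataclass
class TrainingTable:
    """Weighted presence/background rows with their predictor values.

    ``df`` columns: response (0/1), weight, lon, lat, then one column per
    predictor layer. Rows falling on masked predictor cells are dropped at
    assembly and counted in ``n_dropped``.
    """

    df: pd.DataFrame
    species: str
    layer_names: list[str]
    n_dropped: int = 0

    @property
    def weighted_prevalence(self) -> float:
        w, y = self.df["weight"].to_numpy(), self.df["response"].to_numpy()
        return float((w * y).sum() / w.sum())

    def predictors(self) -> np.ndarray:
        return self.df[self.layer_names].to_numpy()

    def subset_layers(self, names: list[str]) -> "TrainingTable":
        keep = ["response", "weight", "lon", "lat"] + list(names)
        return TrainingTable(self.df[keep].copy(), self.species, list(names), self.n_dropped)

    def to_csv(self, path) -> None:
        cols = ["response", "weight"] + self.layer_names + ["lon", "lat"]
        self.df[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, species: str = "") -> "TrainingTable":
        df = pd.read_csv(path)
        for col in ("response", "weight"):
            if col not in df.columns:
                raise ValueError(f"{path}: training table missing column {col!r}")
        layer_names = [c for c in df.columns if c not in ("response", "weight", "lon", "lat")]
        return cls(df, species, layer_names)


def thin_occurrences(occ: OccurrenceSet, min_dist_km: float = 1.0, seed: int = 0) -> OccurrenceSet:
    """Greedy spatial thinning to a minimum pairwise distance.

    Points are shuffled by ``seed`` and accepted in order iff at least
    ``min_dist_km`` from every previously accepted point. The retained set
    is maximal: every removed point lies within ``min_dist_km`` of a kept
    one. On planar grids the threshold is in coordinate units.
    """
    pts = occ.points
    if len(pts) == 0:
        raise ValueError("cannot thin an empty occurrence set")
    if len(pts) == 1:
        return OccurrenceSet(occ.species, pts, thinned=True, min_dist_km=min_dist_km)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pts))
    D = pairwise_distances(pts)
    kept: list[int] = []
    for i in order:
        if all(D[i, j] >= min_dist_km for j in kept):
            kept.append(int(i))
    kept.sort()
    return OccurrenceSet(
        occ.species, pts.subset(np.array(kept)), thinned=True, min_dist_km=min_dist_km
    )


def occupied_ecoregions(occ: OccurrenceSet, ecoregions: Raster) -> frozenset:
    """Labels of the ecoregions containing at least one presence."""
    if len(occ.points) == 0:
        raise ValueError("empty occurrence set")
    cells, rejects = rasterize_points_to_cells(occ.points, ecoregions.grid)
    if rejects:
        logger.warning("%d presence(s) fall outside the ecoregion grid", len(rejects))
    labels = {
        int(ecoregions.values[r, c])
        for r, c in cells
        if not ecoregions.mask[r, c]
    }
    if not labels:
        raise ValueError("all presences fall on masked ecoregion cells")
    return frozenset(labels)


def generate_pseudo_absences(
    ecoregions: Raster,
    occupied_labels: frozenset,
    occ: OccurrenceSet,
    n: int = 5000,
    seed: int = 0,
    allow_presence_cells: bool = False,
) -> BackgroundSet:
    """Uniform sample of n distinct cells from the occupied ecoregions.

    Cells containing a presence are excluded unless
    ``allow_presence_cells`` is set. When fewer candidate cells than ``n``
    exist, all of them are used with a logged warning. Points are jittered
    uniformly within their cell.
    """
    grid = ecoregions.grid
    candidate = np.zeros(grid.shape, dtype=bool)
    for lab in occupied_labels:
        candidate |= (~ecoregions.mask) & (ecoregions.values == lab)
    if not allow_presence_cells:
        cells, _ = rasterize_points_to_cells(occ.points, grid)
        for r, c in cells:
            if 0 <= r < grid.n_rows and 0 <= c < grid.n_cols:
                candidate[r, c] = False
    flat = np.flatnonzero(candidate.ravel())
    if flat.size == 0:
        raise ValueError("no candidate cells available for pseudo-absence sampling")
    n_eff = n
    if flat.size < n:
        logger.warning(
            "only %d candidate cells for %d requested pseudo-absences; using all of them",
            flat.size, n,
        )
        n_eff = flat.size
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat, size=n_eff, replace=False)
    rows, cols = np.unravel_index(chosen, grid.shape)
    x = grid.x_origin + cols * grid.cell_size + rng.uniform(0, grid.cell_size, n_eff)
    y = grid.y_origin - rows * grid.cell_size - rng.uniform(0, grid.cell_size, n_eff)
    pts = PointSet([f"bg_{i}" for i in range(n_eff)], x, y, grid.crs_tag)
    return BackgroundSet(
        species=occ.species,
        points=pts,
        n_requested=n,
        ecoregion_labels_used=frozenset(occupied_labels),
        seed=seed,
    )


def assemble_training_table(
    occ: OccurrenceSet, bg: BackgroundSet, env: EnvStack
) -> TrainingTable:
    """Weighted presence/background rows with predictor values.

    Presences get weight 1; absences get weight n_presence / n_absence so
    the weighted prevalence sum(w*y)/sum(w) equals 0.5 exactly. Rows on
    masked predictor cells are dropped and counted.
    """
    frames = []
    n_dropped = 0
    for pts, response in ((occ.points, 1), (bg.points, 0)):
        cells, rejects = rasterize_points_to_cells(pts, env.grid)
        n_dropped += len(rejects)
        inside = [i for i in range(len(pts)) if i not in set(rejects)]
        rows = np.array([rc[0] for rc in cells], dtype=int)
        cols = np.array([rc[1] for rc in cells], dtype=int)
        if rows.size == 0:
            continue
        X, valid = env.values_at_cells(rows, cols)
        n_dropped += int((~valid).sum())
        sub = np.asarray(inside)[valid]
        frame = pd.DataFrame(X[valid], columns=env.layer_names)
        frame.insert(0, "response", response)
        frame.insert(1, "weight", np.nan)
        frame["lon"] = pts.x[sub]
        frame["lat"] = pts.y[sub]
        frames.append(frame)
    if not frames:
        raise ValueError("no usable training rows")
    df = pd.concat(frames, ignore_index=True)
    n_p = int((df["response"] == 1).sum())
    n_a = int((df["response"] == 0).sum())
    if n_p == 0 or n_a == 0:
        raise ValueError(
            f"training table needs both classes (presences={n_p}, absences={n_a} after drops)"
        )
    df.loc[df["response"] == 1, "weight"] = 1.0
    df.loc[df["response"] == 0, "weight"] = n_p / n_a
    return TrainingTable(df, occ.species, env.layer_names, n_dropped)
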