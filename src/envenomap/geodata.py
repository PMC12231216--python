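"""Grid/point data model, raster and point I/O, geodesic distance, map algebra.

All stages of the pipeline share one spatial convention, fixed here:

* rasters are cell-center registered, row 0 is the northernmost row;
* a point belongs to the cell whose half-open interval
  ``[edge, edge + cell_size)`` contains it (westward/northward edges
  inclusive);
* distances are great-circle kilometres (sphere of radius 6371 km) on
  geographic grids, and plain Euclidean distances in coordinate units on
  synthetic planar grids — the grid's ``crs_tag`` selects the metric;
* nodata propagates by union: any operation touching a masked cell yields
  a masked cell, never a silently filled zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

EARTH_RADIUS_KM = 6371.0

#: crs_tag values treated as planar (Euclidean distances in coordinate units)
PLANAR_TAGS = frozenset({"planar", "synthetic:planar"})


class GridMismatchError(ValueError):
    """Two rasters/point sets that must share a grid or CRS do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid.

    ``x_origin``/``y_origin`` are the coordinates of the grid's north-west
    corner (outer edge, not the first cell center). ``cell_size`` is the
    side of a square cell in degrees (geographic) or planar units.
    """

    n_rows: int
    n_cols: int
    x_origin: float
    y_origin: float
    cell_size: float
    crs_tag: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def is_geographic(self) -> bool:
        return self.crs_tag not in PLANAR_TAGS

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) coordinates of the center of cell (row, col)."""
        x = self.x_origin + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y_origin - (np.asarray(row) + 0.5) * self.cell_size
        return float(x) if np.isscalar(col) else x, float(y) if np.isscalar(row) else y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (xs of shape n_cols, ys of shape n_rows) of cell centers."""
        xs = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def point_to_cell(self, x, y):
        """Vectorized point → (row, col); cells may fall outside the grid."""
        col = np.floor((np.asarray(x, dtype=float) - self.x_origin) / self.cell_size)
        row = np.floor((self.y_origin - np.asarray(y, dtype=float)) / self.cell_size)
        return row.astype(np.int64), col.astype(np.int64)


@dataclass
class Raster:
    """A single-layer grid of real values with a nodata mask.

    ``mask`` is True where the cell carries no data. Unmasked values are
    finite; masked values are irrelevant (kept as NaN on I/O).
    """

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.grid.shape:
                raise ValueError("mask shape does not match grid")
            self.mask = self.mask | ~np.isfinite(self.values)

    def unmasked(self) -> np.ndarray:
        """1-D array of values at unmasked cells (row-major order)."""
        return self.values[~self.mask]

    def with_values(self, values: np.ndarray, extra_mask: np.ndarray | None = None) -> "Raster":
        mask = self.mask if extra_mask is None else (self.mask | extra_mask)
        return Raster(self.grid, values, mask.copy())

    def check_same_grid(self, other: "Raster") -> None:
        if self.grid != other.grid:
            raise GridMismatchError(
                f"grids differ: {self.grid} vs {other.grid}"
            )

    # --- map algebra (union-mask semantics) -------------------------------
    def _binary_op(self, other, op) -> "Raster":
        if isinstance(other, Raster):
            self.check_same_grid(other)
            vals = op(self.values, other.values)
            mask = self.mask | other.mask
        else:
            vals = op(self.values, other)
            mask = self.mask.copy()
        vals = np.where(mask, np.nan, vals)
        return Raster(self.grid, vals, mask)

    def __mul__(self, other):
        return self._binary_op(other, np.multiply)

    __rmul__ = __mul__

    def __add__(self, other):
        return self._binary_op(other, np.add)

    __radd__ = __add__

    def threshold(self, t: float) -> "Raster":
        """Binary raster: 1 where value >= t, 0 elsewhere, mask preserved."""
        vals = np.where(self.mask, np.nan, (self.values >= t).astype(float))
        return Raster(self.grid, vals, self.mask.copy())


@dataclass
class EnvStack:
    """Ordered, named, co-registered raster layers (the predictor stack)."""

    grid: GridSpec
    layers: dict[str, Raster]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("EnvStack requires at least one layer")
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        for name, r in self.layers.items():
            if r.grid != self.grid:
                raise GridMismatchError(f"layer {name!r} is not co-registered with the stack grid")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def combined_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid.shape, dtype=bool)
        for r in self.layers.values():
            mask |= r.mask
        return mask

    def subset(self, names: Sequence[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"unknown layers: {missing}")
        return EnvStack(self.grid, {n: self.layers[n] for n in names})

    def values_at_cells(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictor matrix (n_points, n_layers) at cells; second return is a
        validity flag, False where any layer is masked at that cell."""
        X = np.column_stack([r.values[rows, cols] for r in self.layers.values()])
        valid = ~self.combined_mask[rows, cols]
        return X, valid

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_unmasked_cells, n_layers) matrix and the flat unmasked index."""
        mask = self.combined_mask
        idx = np.flatnonzero(~mask.ravel())
        X = np.column_stack([r.values.ravel()[idx] for r in self.layers.values()])
        return X, idx


@dataclass
class PointSet:
    """Point records with ids, coordinates and optional attributes."""

    ids: list
    x: np.ndarray
    y: np.ndarray
    crs_tag: str = "EPSG:4326"
    attributes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.ids) != len(self.x):
            raise ValueError("ids length must match coordinates")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("point coordinates must be finite")
        if self.crs_tag not in PLANAR_TAGS:
            if (np.abs(self.x) > 180).any() or (np.abs(self.y) > 90).any():
                raise ValueError("geographic coordinates out of range (lon in [-180,180], lat in [-90,90])")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def is_geographic(self) -> bool:
        return self.crs_tag not in PLANAR_TAGS

    def subset(self, index: np.ndarray) -> "PointSet":
        index = np.asarray(index)
        attrs = self.attributes.iloc[index].reset_index(drop=True) if self.attributes is not None else None
        return PointSet([self.ids[i] for i in index], self.x[index], self.y[index], self.crs_tag, attrs)


# ---------------------------------------------------------------------------
# distances


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km on a sphere of radius 6371 km.

    Accepts scalars or broadcastable arrays of lon/lat in degrees.
    """
    lon1, lat1, lon2, lat2 = (np.asarray(a, dtype=float) for a in (lon1, lat1, lon2, lat2))
    for a in (lon1, lat1, lon2, lat2):
        if not np.isfinite(a).all():
            raise ValueError("non-finite coordinate passed to haversine_km")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if d.ndim == 0 else d


def point_distance(x1, y1, x2, y2, crs_tag: str = "EPSG:4326"):
    """CRS-aware distance: haversine km when geographic, Euclidean otherwise."""
    if crs_tag in PLANAR_TAGS:
        x1, y1, x2, y2 = (np.asarray(a, dtype=float) for a in (x1, y1, x2, y2))
        d = np.hypot(x2 - x1, y2 - y1)
        return float(d) if d.ndim == 0 else d
    return haversine_km(x1, y1, x2, y2)


def pairwise_distances(pts: PointSet) -> np.ndarray:
    """Symmetric (n, n) matrix of CRS-aware pairwise distances."""
    return point_distance(
        pts.x[:, None], pts.y[:, None], pts.x[None, :], pts.y[None, :], pts.crs_tag
    )


# ---------------------------------------------------------------------------
# point ↔ cell


def rasterize_points_to_cells(pts: PointSet, grid: GridSpec):
    """Map points to (row, col) cells; out-of-extent points go to a rejects list.

    Returns ``(cells, rejects)`` where ``cells`` is a list of (row, col) for
    in-extent points in input order and ``rejects`` the list of input indices
    that fall outside the grid.
    """
    if len(pts) == 0:
        return [], []
    if pts.crs_tag != grid.crs_tag:
        raise GridMismatchError(
            f"point CRS {pts.crs_tag!r} does not match grid CRS {grid.crs_tag!r}"
        )
    rows, cols = grid.point_to_cell(pts.x, pts.y)
    inside = (rows >= 0) & (rows < grid.n_rows) & (cols >= 0) & (cols < grid.n_cols)
    cells = [(int(r), int(c)) for r, c in zip(rows[inside], cols[inside])]
    rejects = [int(i) for i in np.flatnonzero(~inside)]
    return cells, rejects


def distance_to_points_raster(
    grid: GridSpec, cities: PointSet, mask: np.ndarray | None = None
) -> Raster:
    """Distance (km on geographic grids) from every cell center to the
    nearest point of ``cities``.

    Distances run from the cell center to the exact point location, so a
    cell containing a city gets a small nonzero value unless the city sits
    exactly on the center.
    """
    if len(cities) == 0:
        raise ValueError("no healthcare locations provided")
    if cities.crs_tag != grid.crs_tag:
        raise GridMismatchError("city CRS does not match grid CRS")
    xs, ys = grid.cell_centers()
    X, Y = np.meshgrid(xs, ys)  # (n_rows, n_cols)
    best = np.full(grid.shape, np.inf)
    for cx, cy in zip(cities.x, cities.y):
        d = point_distance(X, Y, cx, cy, grid.crs_tag)
        np.minimum(best, d, out=best)
    m = np.zeros(grid.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    best = np.where(m, np.nan, best)
    return Raster(grid, best, m)


# ---------------------------------------------------------------------------
# raster I/O (TIFF with GeoTIFF georeferencing tags + JSON sidecar description)

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


def write_env_stack(path, stack: EnvStack) -> None:
    """Write a multi-band float32 TIFF; band order and names preserved.

    Nodata cells are stored as NaN. GridSpec, CRS tag and layer names are
    carried in a JSON ImageDescription; ModelPixelScale / ModelTiepoint
    GeoTIFF tags are written so generic GIS tools place the grid correctly.
    """
    g = stack.grid
    data = np.stack(
        [np.where(r.mask, np.nan, r.values).astype(np.float32) for r in stack.layers.values()]
    )
    meta = {
        "layer_names": stack.layer_names,
        "grid": {
            "n_rows": g.n_rows,
            "n_cols": g.n_cols,
            "x_origin": g.x_origin,
            "y_origin": g.y_origin,
            "cell_size": g.cell_size,
            "crs_tag": g.crs_tag,
        },
        "nodata": "nan",
        "distance_units": "km" if g.is_geographic else "grid-units",
    }
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.x_origin, g.y_origin, 0.0)),
    ]
    tifffile.imwrite(
        str(path),
        data[0] if data.shape[0] == 1 else data,  # multi-page for stacks
        photometric="minisblack",
        description=json.dumps(meta),
        extratags=extratags,
    )


def read_env_stack(path) -> EnvStack:
    """Read a stack written by :func:`write_env_stack` (layer order kept)."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
        gmeta = meta["grid"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(f"{path}: missing or unreadable grid metadata") from exc
    grid = GridSpec(
        int(gmeta["n_rows"]), int(gmeta["n_cols"]),
        float(gmeta["x_origin"]), float(gmeta["y_origin"]),
        float(gmeta["cell_size"]), str(gmeta["crs_tag"]),
    )
    data = np.atleast_3d(data)
    if data.shape[-2:] != grid.shape:  # (bands, rows, cols) expected
        data = data.reshape((-1,) + grid.shape)
    names = meta.get("layer_names") or [f"band_{i+1}" for i in range(data.shape[0])]
    layers = {}
    for name, band in zip(names, data):
        band = band.astype(float)
        layers[name] = Raster(grid, band, ~np.isfinite(band))
    return EnvStack(grid, layers)


def write_raster(path, raster: Raster, name: str = "value") -> None:
    write_env_stack(path, EnvStack(raster.grid, {name: raster}))


def read_raster(path) -> Raster:
    stack = read_env_stack(path)
    if len(stack.layers) != 1:
        raise ValueError(f"{path}: expected a single-band raster, found {len(stack.layers)} bands")
    return next(iter(stack.layers.values()))


# ---------------------------------------------------------------------------
# point I/O


def read_occurrences(path, crs_tag: str = "EPSG:4326") -> pd.DataFrame:
    """Occurrence CSV with required columns species, lon, lat."""
    df = pd.read_csv(path)
    missing = [c for c in ("species", "lon", "lat") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: occurrence CSV missing required column(s): {', '.join(missing)}")
    return df


def occurrences_to_pointset(df: pd.DataFrame, species: str | None = None,
                            crs_tag: str = "EPSG:4326") -> PointSet:
    if species is not None:
        df = df[df["species"] == species]
        if df.empty:
            raise ValueError(f"no occurrence records for species {species!r}")
    return PointSet(list(df.index), df["lon"].to_numpy(), df["lat"].to_numpy(), crs_tag)


def write_occurrences(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_points(path, crs_tag: str = "EPSG:4326") -> PointSet:
    """City/facility points from CSV (name,lon,lat) or GeoJSON points."""
    path = Path(path)
    if path.suffix.lower() in {".geojson", ".json"}:
        payload = json.loads(path.read_text())
        feats = payload.get("features", [])
        names, xs, ys = [], [], []
        for i, f in enumerate(feats):
            geom = f.get("geometry", {})
            if geom.get("type") != "Point":
                raise ValueError(f"{path}: feature {i} is not a Point")
            x, y = geom["coordinates"][:2]
            names.append(f.get("properties", {}).get("name", i))
            xs.append(x)
            ys.append(y)
        if not names:
            raise ValueError(f"{path}: no point features found")
        return PointSet(names, np.array(xs), np.array(ys), crs_tag)
    df = pd.read_csv(path)
    missing = [c for c in ("lon", "lat") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: point CSV missing required column(s): {', '.join(missing)}")
    ids = df["name"].tolist() if "name" in df.columns else list(df.index)
    return PointSet(ids, df["lon"].to_numpy(), df["lat"].to_numpy(), crs_tag)


def write_points(path, pts: PointSet) -> None:
    pd.DataFrame({"name": pts.ids, "lon": pts.x, "lat": pts.y}).to_csv(path, index=False)
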