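"""Sting-vulnerability mapping: exposure x distance-to-healthcare.

Vulnerability at a cell is the product of exposure to medically
important species (a binary range map, or the species richness of several
maps) and the distance in km from that cell to the nearest city able to
provide primary health care. Cells inside a suitable range but far from
care score highest; cells outside any range score zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geodata import GridMismatchError, Raster
from .models import BinaryMap


@dataclass
class VulnerabilityMap:
    raster: Raster  # exposure x distance, units: exposure * km
    species: str
    exposure_definition: str  # "binary" | "richness" | "union"
    exposure: Raster
    distance: Raster
    distance_provenance: str = "distance-to-nearest-city (km)"


@dataclass
class VulnerabilityIndex:
    records: pd.DataFrame  # row, col, lon, lat, exposure, distance_km, vulnerability
    summary: dict  # min, q25, median, q75, max


def species_vulnerability(binary: BinaryMap, distance: Raster) -> VulnerabilityMap:
    """Cell-wise product of a single species' binary range and distance."""
    b = binary.raster
    b.check_same_grid(distance)
    return VulnerabilityMap(
        raster=b * distance,
        species=binary.species,
        exposure_definition="binary",
        exposure=b,
        distance=distance,
    )


def combined_vulnerability(
    binaries: Sequence[BinaryMap], distance: Raster, mode: str = "richness"
) -> VulnerabilityMap:
    """All-species vulnerability.

    ``mode="richness"`` (default): exposure = number of species whose
    binary map is 1 at the cell (cumulative hazard). ``mode="union"``:
    exposure = 1 where any species is present. Union <= richness
    cell-wise, with equality wherever richness <= 1.
    """
    binaries = list(binaries)
    if not binaries:
        raise ValueError("at least one binary map required")
    if mode not in ("richness", "union"):
        raise ValueError(f"unknown exposure mode {mode!r}")
    acc = binaries[0].raster
    for b in binaries[1:]:
        acc = acc + b.raster
    if mode == "union":
        acc = acc.threshold(1.0)
    acc.check_same_grid(distance)
    return VulnerabilityMap(
        raster=acc * distance,
        species="combined",
        exposure_definition=mode,
        exposure=acc,
        distance=distance,
    )


def extract_index(vmap: VulnerabilityMap) -> VulnerabilityIndex:
    """One record per unmasked cell plus quartile summary."""
    r = vmap.raster
    unm = ~r.mask
    if not unm.any():
        raise ValueError("vulnerability map is fully masked")
    rows, cols = np.nonzero(unm)
    xs, ys = r.grid.cell_centers()
    vals = r.values[rows, cols]
    records = pd.DataFrame(
        {
            "row": rows,
            "col": cols,
            "lon": xs[cols],
            "lat": ys[rows],
            "exposure": vmap.exposure.values[rows, cols],
            "distance_km": vmap.distance.values[rows, cols],
            "vulnerability": vals,
        }
    )
    qs = np.quantile(vals, [0.0, 0.25, 0.5, 0.75, 1.0])
    summary = dict(zip(["min", "q25", "median", "q75", "max"], map(float, qs)))
    return VulnerabilityIndex(records, summary)
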