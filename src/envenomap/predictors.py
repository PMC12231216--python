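"""Predictor engineering: topographic heterogeneity and VIF screening.

Topographic heterogeneity is the local variability of elevation — here
the population standard deviation of the DEM within a square moving
window (a terrain-ruggedness-index variant is available). Collinearity
among candidate predictors is screened with the variance inflation
factor, VIF = 1/(1-R^2) of each predictor regressed on the others, and a
drop-worst stepwise loop that stops once every retained VIF is below the
threshold (default 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import ndimage

from .geodata import Raster


@dataclass
class VifReport:
    retained: list[str]
    dropped: list[tuple[str, float]]
    final_vifs: dict[str, float]
    threshold: float = 10.0

    def to_dict(self) -> dict:
        return {
            "retained": self.retained,
            "dropped": [{"name": n, "vif_at_drop": v} for n, v in self.dropped],
            "final_vifs": self.final_vifs,
            "threshold": self.threshold,
        }


def topographic_heterogeneity(dem: Raster, window: int = 3, metric: str = "sd") -> Raster:
    """Windowed heterogeneity of a DEM, mask-aware.

    ``metric="sd"`` (default): population standard deviation of the
    unmasked elevations in the window x window neighborhood.
    ``metric="tri"``: terrain ruggedness index — mean absolute difference
    between the center cell and its unmasked neighbors (masked where the
    center is masked).

    A cell whose entire neighborhood is masked becomes masked. Neighborhoods
    are truncated at the grid edge.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    valid = (~dem.mask).astype(float)
    if not valid.any():
        raise ValueError("DEM is fully masked")
    v = np.where(dem.mask, 0.0, dem.values)
    kernel = np.ones((window, window))
    n = ndimage.correlate(valid, kernel, mode="constant", cval=0.0)
    s1 = ndimage.correlate(v, kernel, mode="constant", cval=0.0)
    if metric == "sd":
        s2 = ndimage.correlate(v * v, kernel, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = s1 / n
            var = np.clip(s2 / n - mean**2, 0.0, None)
            out = np.sqrt(var)
        out_mask = n == 0
    elif metric == "tri":
        with np.errstate(invalid="ignore", divide="ignore"):
            # mean |center - neighbor| cannot be windowed exactly in one
            # convolution; do it with an explicit neighbor loop (window 3..9
            # at analysis scales, so the loop over offsets is cheap)
            half = window // 2
            acc = np.zeros_like(v)
            cnt = np.zeros_like(v)
            for dr in range(-half, half + 1):
                for dc in range(-half, half + 1):
                    if dr == 0 and dc == 0:
                        continue
                    shifted = np.full_like(v, np.nan)
                    sv = np.full_like(valid, 0.0)
                    src = (
                        slice(max(0, -dr), v.shape[0] - max(0, dr)),
                        slice(max(0, -dc), v.shape[1] - max(0, dc)),
                    )
                    dst = (
                        slice(max(0, dr), v.shape[0] - max(0, -dr)),
                        slice(max(0, dc), v.shape[1] - max(0, -dc)),
                    )
                    shifted[dst] = v[src]
                    sv[dst] = valid[src]
                    acc += np.where(sv > 0, np.abs(dem.values - shifted), 0.0)
                    cnt += sv
            out = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
        out_mask = dem.mask | (cnt == 0)
    else:
        raise ValueError(f"unknown heterogeneity metric {metric!r}")
    out = np.where(out_mask, np.nan, out)
    return Raster(dem.grid, out, out_mask)


def compute_vif(table: pd.DataFrame, name: str) -> float:
    """VIF of one predictor regressed on all others (with intercept).

    Perfect collinearity is reported as ``inf``; a constant predictor is
    rejected by name.
    """
    if name not in table.columns:
        raise KeyError(f"unknown predictor {name!r}")
    if table.shape[1] < 2:
        raise ValueError("VIF requires at least two predictors")
    if table.shape[0] < table.shape[1] + 1:
        raise ValueError("VIF requires more rows than predictors")
    for col in table.columns:
        if np.std(table[col].to_numpy()) == 0:
            raise ValueError(f"predictor {col!r} is constant")
    y = table[name].to_numpy(dtype=float)
    X = sm.add_constant(table.drop(columns=[name]).to_numpy(dtype=float))
    r2 = sm.OLS(y, X).fit().rsquared
    if 1.0 - r2 < 1e-12:
        return float("inf")
    return float(1.0 / (1.0 - r2))


def stepwise_vif_select(table: pd.DataFrame, threshold: float = 10.0) -> VifReport:
    """Drop-worst stepwise VIF selection.

    While any VIF >= threshold, remove the predictor with the largest VIF
    (ties broken by dropping the later-listed predictor, keeping
    earlier-listed ones) and recompute. Stops when all retained VIFs are
    below the threshold or a single predictor remains.
    """
    current = list(table.columns)
    if len(current) < 2:
        raise ValueError("VIF selection requires at least two predictors")
    dropped: list[tuple[str, float]] = []
    while len(current) > 1:
        vifs = {name: compute_vif(table[current], name) for name in current}
        worst_val = max(vifs.values())
        if worst_val < threshold:
            break
        # among ties at the max, drop the later-listed predictor
        worst = max(
            (name for name in current if vifs[name] == worst_val),
            key=current.index,
        )
        dropped.append((worst, worst_val))
        current.remove(worst)
    if len(current) > 1:
        final = {name: compute_vif(table[current], name) for name in current}
    else:
        final = {current[0]: 1.0}
    return VifReport(retained=current, dropped=dropped, final_vifs=final, threshold=threshold)
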