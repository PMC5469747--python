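"""Daily potential-feeding-habitat masks and proximity statistics.

Fin whales aggregate near chlorophyll-a fronts over deep water with modest
surface chl-a. A cell counts as potential feeding habitat on a given day
when all of these hold:

* it lies within a small dilation of a detected chl-a front,
* its chl-a concentration falls in a configured window (default
  0.05–0.5 mg m⁻³; the upper bound is the published "low chlorophyll"
  criterion),
* the water is at least 200 m deep, and
* it is a sea cell.

The front detector is a deliberately simple proxy for the published
multi-scale algorithm: a threshold on the horizontal gradient magnitude of
log chl-a (per 100 km), optionally dilated by a few cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GridSpec, KM_PER_DEG


@dataclass
class HabitatConfig:
    chl_min: float = 0.05  # mg m^-3
    chl_max: float = 0.5  # mg m^-3, the "low chlorophyll" upper bound
    depth_min_m: float = 200.0
    gradient_threshold: float = 0.5  # |∇ ln chl| per 100 km
    dilate_cells: int = 2


@dataclass
class HabitatStack:
    """Binary daily suitability masks on a shared grid."""

    grid: GridSpec
    days: list  # hashable day keys (e.g. datetime.date or int)
    masks: np.ndarray  # (n_days, ny, nx) bool
    config: HabitatConfig = field(default_factory=HabitatConfig)

    def mask_for(self, day) -> np.ndarray:
        try:
            i = self.days.index(day)
        except ValueError:
            raise KeyError(f"no habitat mask for day {day!r}") from None
        return self.masks[i]


@dataclass
class ProximityResult:
    distances_km: pd.Series  # per daily position; NaN when that day had no habitat
    threshold_km: float
    n_positions: int
    n_excluded_empty_days: int

    @property
    def fraction_within(self) -> float:
        valid = self.distances_km.dropna()
        if len(valid) == 0:
            return float("nan")
        return float((valid < self.threshold_km).mean())


def metric_gradient_log(chla: np.ndarray, grid: GridSpec) -> np.ndarray:
    """|∇ ln chl-a| per 100 km, centred finite differences on the sphere."""
    if grid.ny < 3 or grid.nx < 3:
        raise ValueError("grid must be at least 3x3 for gradients")
    logc = np.log(np.maximum(np.asarray(chla, float), 1e-12))
    dy_km = grid.dlat * KM_PER_DEG
    dx_km = grid.dlon * KM_PER_DEG * np.cos(np.radians(grid.lat_centers))
    gy = np.gradient(logc, axis=0) / dy_km
    gx = np.gradient(logc, axis=1) / dx_km[:, None]
    return 100.0 * np.hypot(gx, gy)


def detect_fronts(chla: np.ndarray, grid: GridSpec, config: HabitatConfig | None = None) -> np.ndarray:
    """Flag cells whose log-chl-a gradient magnitude reaches the threshold."""
    config = config or HabitatConfig()
    grad = metric_gradient_log(chla, grid)
    mask = grad >= config.gradient_threshold
    if config.dilate_cells > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, iterations=config.dilate_cells)
    return mask


def habitat_mask(
    chla: np.ndarray,
    fronts: np.ndarray,
    depth: np.ndarray,
    sea: np.ndarray | None = None,
    config: HabitatConfig | None = None,
) -> np.ndarray:
    """Daily suitability: front-adjacent ∧ chl window ∧ deep enough ∧ sea."""
    config = config or HabitatConfig()
    layers = [np.asarray(a) for a in (chla, fronts, depth)]
    if len({a.shape for a in layers}) != 1:
        raise ValueError("chl-a, front and depth layers must share one grid")
    if sea is None:
        sea = np.ones_like(layers[0], dtype=bool)
    elif np.asarray(sea).shape != layers[0].shape:
        raise ValueError("sea mask must share the grid")
    chl_ok = (chla >= config.chl_min) & (chla <= config.chl_max)
    return np.asarray(fronts, bool) & chl_ok & (depth >= config.depth_min_m) & np.asarray(sea, bool)


def build_habitat_stack(
    chla_stack: np.ndarray,
    depth: np.ndarray,
    grid: GridSpec,
    days: list,
    sea: np.ndarray | None = None,
    config: HabitatConfig | None = None,
) -> HabitatStack:
    config = config or HabitatConfig()
    masks = np.empty((len(days), *grid.shape), dtype=bool)
    for i in range(len(days)):
        fronts = detect_fronts(chla_stack[i], grid, config)
        masks[i] = habitat_mask(chla_stack[i], fronts, depth, sea, config)
    return HabitatStack(grid=grid, days=list(days), masks=masks, config=config)


def habitat_frequency(stack: HabitatStack, window: list) -> np.ndarray:
    """Per-cell fraction of window days on which the cell was suitable."""
    if not window:
        raise ValueError("empty day window")
    missing = [d for d in window if d not in stack.days]
    if missing:
        raise KeyError(f"days missing from habitat stack: {missing}")
    idx = [stack.days.index(d) for d in window]
    return stack.masks[idx].mean(axis=0)


def habitat_area_fraction(mask: np.ndarray, region, grid: GridSpec, sea: np.ndarray | None = None) -> float:
    """Percentage of a region's sea area that is suitable.

    ``region`` is a shapely polygon in lon/lat; cells count by centre-in-region.
    """
    import shapely

    LON, LAT = grid.center_mesh()
    inside = shapely.contains_xy(region, LON.ravel(), LAT.ravel()).reshape(grid.shape)
    if sea is None:
        sea = np.ones(grid.shape, dtype=bool)
    areas = grid.cell_areas_km2()
    denom = float(areas[inside & sea].sum())
    if denom == 0:
        raise ValueError("region does not intersect the grid's sea cells")
    num = float(areas[inside & sea & np.asarray(mask, bool)].sum())
    return 100.0 * num / denom


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance (km), R = 6371 km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * 6371.0 * np.arcsin(np.sqrt(a))


def daily_positions(positions: pd.DataFrame) -> pd.DataFrame:
    """One position per platform per day: the daily mean location.

    Expects columns ptt, time (datetime), lon, lat; returns ptt, day, lon, lat.
    """
    df = positions.copy()
    df["day"] = pd.to_datetime(df["time"]).dt.date
    out = df.groupby(["ptt", "day"], as_index=False)[["lon", "lat"]].mean()
    return out


def distance_to_habitat(
    positions: pd.DataFrame,
    stack: HabitatStack,
    threshold_km: float = 7.0,
) -> ProximityResult:
    """Distance from each daily position to the nearest suitable cell centre.

    A position whose own cell is suitable scores 0 km. Days with an empty
    habitat mask contribute missing distances (excluded from the summary
    fraction, but counted). The summary is the fraction strictly below the
    threshold.
    """
    grid = stack.grid
    LON, LAT = grid.center_mesh()
    dists = np.full(len(positions), np.nan)
    n_empty = 0
    for i, row in enumerate(positions.itertuples(index=False)):
        mask = stack.mask_for(row.day)
        if not mask.any():
            n_empty += 1
            continue
        try:
            r, c = grid.cell_of(row.lon, row.lat)
            if mask[r, c]:
                dists[i] = 0.0
                continue
        except ValueError:
            pass  # position outside the grid: fall through to nearest-cell scan
        d = haversine_km(row.lon, row.lat, LON[mask], LAT[mask])
        dists[i] = float(d.min())
    return ProximityResult(
        distances_km=pd.Series(dists, index=positions.index),
        threshold_km=threshold_km,
        n_positions=len(positions),
        n_excluded_empty_days=n_empty,
    )
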