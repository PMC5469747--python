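"""Shipping-traffic extraction and home-range overlap percentages.

The vessel-density product is an integer raster (values 0–409 on ~1 km²
cells). "High-traffic" cells are those inside the minimum bounding geometry
whose value reaches a threshold rule — by default the 90th percentile of the
nonzero in-MBG values, or an absolute cut. Overlap is reported as the
percentage of each home range (THR, CHR) covered by high-traffic area, all
geometry in the home-range module's equal-area plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon

from .grids import ProjGrid
from .homerange import HomeRanges, _cells_to_polygons


@dataclass
class TrafficRaster:
    grid: ProjGrid
    values: np.ndarray  # (ny, nx) integers in [0, 409]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError("traffic raster shape does not match grid")
        if self.values.min() < 0 or self.values.max() > 409:
            raise ValueError("traffic values must lie in [0, 409]")


@dataclass
class OverlapReport:
    pct_thr: float
    pct_chr: float
    thr_area_km2: float
    chr_area_km2: float
    thr_intersection_km2: float
    chr_intersection_km2: float
    threshold_rule: dict

    def to_dict(self) -> dict:
        return {
            "pct_thr": self.pct_thr,
            "pct_chr": self.pct_chr,
            "areas_km2": {
                "thr": self.thr_area_km2,
                "chr": self.chr_area_km2,
                "high_traffic_and_thr": self.thr_intersection_km2,
                "high_traffic_and_chr": self.chr_intersection_km2,
            },
            "threshold_rule": self.threshold_rule,
        }


def extract_high_traffic(
    raster: TrafficRaster,
    mbg: Polygon,
    percentile: float | None = 90.0,
    absolute_threshold: float | None = None,
) -> tuple[object, np.ndarray, dict]:
    """High-traffic cells inside the MBG, vectorised to polygons.

    Default rule: value ≥ the ``percentile`` of nonzero in-MBG values.
    Passing ``absolute_threshold`` switches to value ≥ that cut. Returns
    (polygons, cell mask, rule description).
    """
    grid = raster.grid
    X, Y = np.meshgrid(grid.x_centers, grid.y_centers)
    inside = shapely.contains_xy(mbg, X.ravel(), Y.ravel()).reshape(grid.shape)
    if not inside.any():
        raise ValueError("traffic raster does not intersect the bounding geometry")
    vals = raster.values
    if absolute_threshold is not None:
        thr = float(absolute_threshold)
        rule = {"kind": "absolute", "threshold": thr}
    else:
        nonzero = vals[inside & (vals > 0)]
        if len(nonzero) == 0:
            mask = np.zeros(grid.shape, dtype=bool)
            return _cells_to_polygons(mask, grid), mask, {
                "kind": "percentile", "percentile": percentile, "threshold": None,
            }
        thr = float(np.percentile(nonzero, percentile))
        rule = {"kind": "percentile", "percentile": percentile, "threshold": thr}
    mask = inside & (vals >= thr)
    return _cells_to_polygons(mask, grid), mask, rule


def overlap_percentages(
    home: HomeRanges,
    high_traffic,  # shapely (Multi)Polygon
    mbg: Polygon,
    rule: dict | None = None,
) -> OverlapReport:
    """Percentage of THR and CHR area covered by high-traffic area.

    All geometries are clipped to the MBG; the denominator is the (clipped)
    home-range area, not the MBG area.
    """
    thr_g = home.thr_polygons.intersection(mbg)
    chr_g = home.chr_polygons.intersection(mbg)
    if thr_g.area == 0 or chr_g.area == 0:
        raise ValueError("home range has zero area inside the bounding geometry")
    traffic_g = high_traffic.intersection(mbg)
    thr_int = thr_g.intersection(traffic_g).area
    chr_int = chr_g.intersection(traffic_g).area
    return OverlapReport(
        pct_thr=100.0 * thr_int / thr_g.area,
        pct_chr=100.0 * chr_int / chr_g.area,
        thr_area_km2=thr_g.area,
        chr_area_km2=chr_g.area,
        thr_intersection_km2=thr_int,
        chr_intersection_km2=chr_int,
        threshold_rule=rule or {},
    )


def overlap_by_cells(
    home: HomeRanges,
    traffic_mask: np.ndarray,
    ud_grid_mask_thr: np.ndarray | None = None,
) -> tuple[float, float]:
    """Raster-route overlap: cell-count ratio on a shared grid.

    Cross-checks the polygon route when the traffic raster and UD share a
    grid. Returns (pct_thr, pct_chr).
    """
    thr_cells = home.thr_cells
    chr_cells = home.chr_cells
    if traffic_mask.shape != thr_cells.shape:
        raise ValueError("traffic mask must share the UD grid")
    pct_thr = 100.0 * (thr_cells & traffic_mask).sum() / thr_cells.sum()
    pct_chr = 100.0 * (chr_cells & traffic_mask).sum() / chr_cells.sum()
    return float(pct_thr), float(pct_chr)
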