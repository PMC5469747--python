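"""Kernel utilisation distributions and isopleth home ranges.

Positions are projected into a local Lambert azimuthal equal-area plane
(kilometres) centred on their centroid, so probability masses and areas are
area-true at basin scale. The utilisation distribution (UD) is a Gaussian
product-kernel density on a regular grid with per-axis Silverman bandwidths;
physical barriers (coastline) are handled by zeroing barrier cells and
renormalising to unit mass over the sea. Home ranges are superlevel sets of
the UD: the smallest set of cells whose cumulative mass reaches the level —
50% for the core home range (CHR), 90% for the total home range (THR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint, Polygon, box
from shapely.ops import unary_union

from .grids import EARTH_RADIUS_KM, ProjGrid


@dataclass(frozen=True)
class EqualAreaProjection:
    """Lambert azimuthal equal-area projection centred at (lon0, lat0), km."""

    lon0: float
    lat0: float

    def forward(self, lonlat: np.ndarray) -> np.ndarray:
        ll = np.atleast_2d(np.asarray(lonlat, float))
        lam = np.radians(ll[:, 0] - self.lon0)
        phi = np.radians(ll[:, 1])
        phi0 = np.radians(self.lat0)
        denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
        k = np.sqrt(2.0 / denom)
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam)
        y = EARTH_RADIUS_KM * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam)
        )
        return np.column_stack([x, y])

    def inverse(self, xy: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(xy, float)) / EARTH_RADIUS_KM
        rho = np.hypot(p[:, 0], p[:, 1])
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
        phi0 = np.radians(self.lat0)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(
                rho == 0,
                phi0,
                np.arcsin(np.cos(c) * np.sin(phi0) + p[:, 1] * np.sin(c) * np.cos(phi0) / np.where(rho == 0, 1, rho)),
            )
            lam = np.arctan2(
                p[:, 0] * np.sin(c),
                rho * np.cos(phi0) * np.cos(c) - p[:, 1] * np.sin(phi0) * np.sin(c),
            )
        lam = np.where(rho == 0, 0.0, lam)
        return np.column_stack([self.lon0 + np.degrees(lam), np.degrees(phi)])


def project_positions(lonlat: np.ndarray) -> tuple[np.ndarray, EqualAreaProjection]:
    """Project lon/lat positions about their centroid; returns (xy_km, proj)."""
    ll = np.asarray(lonlat, float)
    proj = EqualAreaProjection(lon0=float(ll[:, 0].mean()), lat0=float(ll[:, 1].mean()))
    return proj.forward(ll), proj


def minimum_bounding_geometry(positions_xy: np.ndarray) -> Polygon:
    """Convex hull (the minimum bounding geometry) of projected positions."""
    pts = np.asarray(positions_xy, float)
    if len(pts) < 3:
        raise ValueError("need at least 3 positions for a bounding geometry")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("positions are collinear; no areal bounding geometry")
    return hull


@dataclass
class UDGrid:
    """Gridded utilisation distribution; density integrates to 1 over sea."""

    grid: ProjGrid
    density: np.ndarray  # (ny, nx), km^-2
    barrier: np.ndarray  # (ny, nx) bool; density is zero there
    bandwidth_km: tuple[float, float]

    def total_mass(self) -> float:
        return float(self.density.sum() * self.grid.cell_area_km2)


@dataclass
class HomeRanges:
    chr_polygons: object  # shapely (Multi)Polygon
    thr_polygons: object
    chr_area_km2: float
    thr_area_km2: float
    chr_mass: float
    thr_mass: float
    chr_cells: np.ndarray  # bool masks on the UD grid
    thr_cells: np.ndarray


def silverman_bandwidths(positions_xy: np.ndarray) -> tuple[float, float]:
    """Per-axis Gaussian reference-rule bandwidths h_j = σ_j n^(−1/6)."""
    pts = np.asarray(positions_xy, float)
    n = len(pts)
    sd = pts.std(axis=0, ddof=1)
    h = sd * n ** (-1.0 / 6.0)
    return (float(max(h[0], 1e-6)), float(max(h[1], 1e-6)))


def default_grid(positions_xy: np.ndarray, bandwidth: tuple[float, float], margin_bw: float = 4.0, target_cells: int = 200) -> ProjGrid:
    pts = np.asarray(positions_xy, float)
    hx, hy = bandwidth
    x_min, y_min = pts.min(axis=0) - margin_bw * np.array([hx, hy])
    x_max, y_max = pts.max(axis=0) + margin_bw * np.array([hx, hy])
    dx = max((x_max - x_min), (y_max - y_min)) / target_cells
    nx = int(np.ceil((x_max - x_min) / dx))
    ny = int(np.ceil((y_max - y_min) / dx))
    return ProjGrid(x0=float(x_min), y0=float(y_min), dx=float(dx), dy=float(dx), nx=nx, ny=ny)


def kde_ud(
    positions_xy: np.ndarray,
    grid: ProjGrid | None = None,
    bandwidth_km: tuple[float, float] | None = None,
    barrier_mask: np.ndarray | None = None,
) -> UDGrid:
    """Gaussian product-kernel UD on a grid, barrier-masked and renormalised.

    The kernel is separable, so the density is the product of one-dimensional
    kernel matrices: D = Ky @ Kx^T / n, evaluated at cell centres. Barrier
    cells are zeroed and the remaining mass rescaled to integrate to 1.
    """
    pts = np.asarray(positions_xy, float)
    if len(np.unique(pts, axis=0)) < 2:
        raise ValueError("need at least 2 distinct positions")
    bw = bandwidth_km or silverman_bandwidths(pts)
    grid = grid or default_grid(pts, bw)
    hx, hy = bw

    gx = grid.x_centers
    gy = grid.y_centers
    kx = np.exp(-0.5 * ((gx[:, None] - pts[None, :, 0]) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * ((gy[:, None] - pts[None, :, 1]) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
    density = (ky @ kx.T) / len(pts)  # (ny, nx)

    if barrier_mask is None:
        barrier_mask = np.zeros(grid.shape, dtype=bool)
    else:
        barrier_mask = np.asarray(barrier_mask, dtype=bool)
        if barrier_mask.shape != grid.shape:
            raise ValueError("barrier mask shape does not match grid")
    density = np.where(barrier_mask, 0.0, density)
    mass = density.sum() * grid.cell_area_km2
    if mass <= 0:
        raise ValueError("all probability mass falls on barrier cells")
    density = density / mass
    return UDGrid(grid=grid, density=density, barrier=barrier_mask, bandwidth_km=(hx, hy))


def _cells_to_polygons(cells: np.ndarray, grid: ProjGrid):
    boxes = []
    ys, xs = np.nonzero(cells)
    for r, c in zip(ys, xs):
        boxes.append(
            box(
                grid.x0 + c * grid.dx,
                grid.y0 + r * grid.dy,
                grid.x0 + (c + 1) * grid.dx,
                grid.y0 + (r + 1) * grid.dy,
            )
        )
    return unary_union(boxes) if boxes else Polygon()


def isopleth(ud: UDGrid, level: float) -> tuple[object, float, np.ndarray]:
    """Smallest superlevel set of cells with cumulative mass ≥ level.

    Cells are ranked by density (descending), ties broken by flat cell index
    for determinism. Returns (polygons, attained mass, cell mask).
    """
    if not 0.0 < level <= 1.0:
        raise ValueError(f"isopleth level must be in (0, 1], got {level}")
    flat = ud.density.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    masses = flat[order] * ud.grid.cell_area_km2
    cum = np.cumsum(masses)
    n_cells = int(np.searchsorted(cum, level - 1e-12) + 1)
    n_cells = min(n_cells, int((flat > 0).sum()))
    chosen = order[:n_cells]
    mask = np.zeros(flat.size, dtype=bool)
    mask[chosen] = True
    mask = mask.reshape(ud.density.shape)
    attained = float(cum[n_cells - 1]) if n_cells > 0 else 0.0
    return _cells_to_polygons(mask, ud.grid), attained, mask


def home_ranges(ud: UDGrid, core_level: float = 0.5, total_level: float = 0.9) -> HomeRanges:
    """Core (50%) and total (90%) isopleth home ranges with km² areas."""
    chr_poly, chr_mass, chr_cells = isopleth(ud, core_level)
    thr_poly, thr_mass, thr_cells = isopleth(ud, total_level)
    area = ud.grid.cell_area_km2
    return HomeRanges(
        chr_polygons=chr_poly,
        thr_polygons=thr_poly,
        chr_area_km2=float(chr_cells.sum() * area),
        thr_area_km2=float(thr_cells.sum() * area),
        chr_mass=chr_mass,
        thr_mass=thr_mass,
        chr_cells=chr_cells,
        thr_cells=thr_cells,
    )
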