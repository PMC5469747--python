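"""Gridded-layer containers and plain-text I/O.

Two grid flavours are used across the pipeline:

* :class:`GridSpec` — a regular longitude/latitude grid (degrees, WGS84) used
  by the habitat layers (chlorophyll-a, bathymetry, suitability masks).
* :class:`ProjGrid` — a regular grid in a local equal-area plane (kilometres)
  used by the utilisation-distribution and traffic-overlap computations.

Layers are written as plain-text arrays (``numpy.savetxt``) with a JSON
sidecar describing the grid, so every artefact stays human-readable.
Array rows run south→north (row 0 is the southernmost row).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0
KM_PER_DEG = np.pi / 180.0 * EARTH_RADIUS_KM  # 111.1949... km per degree of latitude


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid. ``lon0``/``lat0`` are the west/south *edges*."""

    lon0: float
    lat0: float
    dlon: float
    dlat: float
    nx: int
    ny: int

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon0 + (np.arange(self.nx) + 0.5) * self.dlon

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat0 + (np.arange(self.ny) + 0.5) * self.dlat

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def cell_areas_km2(self) -> np.ndarray:
        """Per-row cell areas (km^2), broadcast to the full grid shape."""
        dy = self.dlat * KM_PER_DEG
        dx = self.dlon * KM_PER_DEG * np.cos(np.radians(self.lat_centers))
        return np.broadcast_to((dy * dx)[:, None], self.shape).copy()

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.lon_centers, self.lat_centers)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; raises if outside."""
        col = int(np.floor((lon - self.lon0) / self.dlon))
        row = int(np.floor((lat - self.lat0) / self.dlat))
        if not (0 <= col < self.nx and 0 <= row < self.ny):
            raise ValueError(f"point ({lon}, {lat}) outside grid")
        return row, col


@dataclass(frozen=True)
class ProjGrid:
    """Regular grid in a local equal-area plane, units km. Edges at x0/y0."""

    x0: float
    y0: float
    dx: float
    dy: float
    nx: int
    ny: int

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.dy

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def cell_area_km2(self) -> float:
        return self.dx * self.dy


def write_grid(path: str | Path, values: np.ndarray, grid: GridSpec | ProjGrid) -> None:
    """Write a layer as text with a ``.json`` grid-definition sidecar."""
    path = Path(path)
    if values.shape != grid.shape:
        raise ValueError(f"layer shape {values.shape} != grid shape {grid.shape}")
    np.savetxt(path, values, fmt="%.10g")
    sidecar = {"kind": type(grid).__name__, **asdict(grid)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_grid(path: str | Path) -> tuple[np.ndarray, GridSpec | ProjGrid]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    kind = meta.pop("kind")
    grid = {"GridSpec": GridSpec, "ProjGrid": ProjGrid}[kind](**meta)
    values = np.loadtxt(path, ndmin=2)
    if values.shape != grid.shape:
        raise ValueError(f"layer shape {values.shape} != sidecar shape {grid.shape}")
    return values, grid
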