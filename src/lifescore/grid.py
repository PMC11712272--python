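"""Geographic grid support: georeferencing, latitude-dependent pixel areas,
and the fine-pixel -> coarse-cell index mapping shared by all raster stages.

The package works on a plate-carree (EPSG:4326) grid. Scores are produced at a
coarse resolution expressed in arc-minutes (1 arc-min in the headline maps,
which is ~1.86 km on a side and ~3.4 km^2 at the equator on the spherical Earth
model used here); habitat suitability is evaluated on a finer subdivision of
each coarse cell, controlled by an integer ``fine_factor``.

Rows run north to south (row 0 is the northernmost), columns west to east.
Cell intervals are half-open: a coordinate on a shared edge belongs to the
cell south/east of that edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: WGS84 equatorial radius, km.  A sphere of this radius reproduces the
#: conventional printed figures for a 1 arc-min cell (1.86 km side, 3.4 km^2).
EARTH_RADIUS_KM = 6378.137


@dataclass(frozen=True)
class GridSpec:
    """Extent and resolution of a co-registered raster stack.

    Parameters
    ----------
    lat_min, lat_max, lon_min, lon_max:
        Grid extent in decimal degrees (cell-edge aligned).
    coarse_res:
        Side of a coarse (output) cell in arc-minutes.
    fine_factor:
        Integer number of fine pixels per coarse-cell side.
    earth_radius:
        Radius of the spherical Earth model, km.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    coarse_res: float = 1.0
    fine_factor: int = 1
    earth_radius: float = EARTH_RADIUS_KM

    def __post_init__(self) -> None:
        if not self.lat_max > self.lat_min:
            raise ValueError("lat_max must exceed lat_min")
        if not self.lon_max > self.lon_min:
            raise ValueError("lon_max must exceed lon_min")
        if self.coarse_res <= 0:
            raise ValueError("coarse_res must be positive")
        if int(self.fine_factor) != self.fine_factor or self.fine_factor < 1:
            raise ValueError("fine_factor must be an integer >= 1")
        deg = self.coarse_res / 60.0
        for span, name in (
            (self.lat_max - self.lat_min, "latitude"),
            (self.lon_max - self.lon_min, "longitude"),
        ):
            n = span / deg
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"{name} extent is not an exact multiple of coarse_res"
                )

    # ---- derived dimensions -------------------------------------------------

    @property
    def coarse_deg(self) -> float:
        """Coarse cell side in degrees."""
        return self.coarse_res / 60.0

    @property
    def fine_deg(self) -> float:
        """Fine pixel side in degrees."""
        return self.coarse_deg / self.fine_factor

    @property
    def n_coarse_rows(self) -> int:
        return round((self.lat_max - self.lat_min) / self.coarse_deg)

    @property
    def n_coarse_cols(self) -> int:
        return round((self.lon_max - self.lon_min) / self.coarse_deg)

    @property
    def n_fine_rows(self) -> int:
        return self.n_coarse_rows * self.fine_factor

    @property
    def n_fine_cols(self) -> int:
        return self.n_coarse_cols * self.fine_factor

    @property
    def fine_shape(self) -> tuple[int, int]:
        return (self.n_fine_rows, self.n_fine_cols)

    @property
    def coarse_shape(self) -> tuple[int, int]:
        return (self.n_coarse_rows, self.n_coarse_cols)

    # ---- coordinates --------------------------------------------------------

    def fine_lat_center(self, row: int | np.ndarray) -> float | np.ndarray:
        """Latitude of fine-pixel centers for the given row(s)."""
        return self.lat_max - (np.asarray(row) + 0.5) * self.fine_deg

    def fine_lon_center(self, col: int | np.ndarray) -> float | np.ndarray:
        return self.lon_min + (np.asarray(col) + 0.5) * self.fine_deg

    def coarse_lat_center(self, row: int | np.ndarray) -> float | np.ndarray:
        return self.lat_max - (np.asarray(row) + 0.5) * self.coarse_deg

    def coarse_lon_center(self, col: int | np.ndarray) -> float | np.ndarray:
        return self.lon_min + (np.asarray(col) + 0.5) * self.coarse_deg

    def to_dict(self) -> dict:
        return {
            "lat_min": self.lat_min,
            "lat_max": self.lat_max,
            "lon_min": self.lon_min,
            "lon_max": self.lon_max,
            "coarse_res": self.coarse_res,
            "fine_factor": self.fine_factor,
            "earth_radius": self.earth_radius,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


def pixel_area_km2(grid: GridSpec, row: int) -> float:
    """Area in km^2 of a fine pixel in the given row.

    On a sphere, a pixel of angular side ``d`` degrees centered at latitude
    ``phi`` has area ``s^2 * cos(phi)`` with ``s = 2*pi*R*d/360`` — the
    meridional side is latitude-independent and the zonal side shrinks with
    ``cos(phi)``. Area depends only on the row, never the column.
    """
    if not 0 <= row < grid.n_fine_rows:
        raise IndexError(f"row {row} out of range [0, {grid.n_fine_rows})")
    s = 2.0 * math.pi * grid.earth_radius * grid.fine_deg / 360.0
    lat = grid.lat_max - (row + 0.5) * grid.fine_deg
    return s * s * math.cos(math.radians(lat))


def fine_row_areas(grid: GridSpec) -> np.ndarray:
    """Vector of fine-pixel areas (km^2) by row, length ``n_fine_rows``."""
    s = 2.0 * math.pi * grid.earth_radius * grid.fine_deg / 360.0
    lats = grid.fine_lat_center(np.arange(grid.n_fine_rows))
    return s * s * np.cos(np.radians(lats))


def fine_area_raster(grid: GridSpec) -> np.ndarray:
    """Fine raster of pixel areas (km^2), shape ``grid.fine_shape``."""
    return np.broadcast_to(
        fine_row_areas(grid)[:, None], grid.fine_shape
    ).copy()


def coarse_cell_areas(grid: GridSpec) -> np.ndarray:
    """Coarse raster of cell areas (km^2), the exact sum of member pixels."""
    return aggregate_fine_to_coarse(fine_area_raster(grid), grid.fine_factor)


def coarse_index(grid: GridSpec, fine_row: int, fine_col: int) -> tuple[int, int]:
    """Map a fine pixel to its (coarse_row, coarse_col) cell by integer division."""
    if not 0 <= fine_row < grid.n_fine_rows:
        raise IndexError(f"fine_row {fine_row} out of range")
    if not 0 <= fine_col < grid.n_fine_cols:
        raise IndexError(f"fine_col {fine_col} out of range")
    return fine_row // grid.fine_factor, fine_col // grid.fine_factor


def aggregate_fine_to_coarse(arr: np.ndarray, fine_factor: int) -> np.ndarray:
    """Sum fine-pixel values into their coarse cells (exact, lossless).

    ``arr`` has shape (R*f, C*f); the result has shape (R, C).
    """
    r, c = arr.shape
    f = fine_factor
    if r % f or c % f:
        raise ValueError("array shape is not a multiple of fine_factor")
    return arr.reshape(r // f, f, c // f, f).sum(axis=(1, 3))


def coarse_cell_fine_slice(grid: GridSpec, coarse_row: int, coarse_col: int
                           ) -> tuple[slice, slice]:
    """Fine-index slices covering one coarse cell."""
    f = grid.fine_factor
    if not 0 <= coarse_row < grid.n_coarse_rows:
        raise IndexError(f"coarse_row {coarse_row} out of range")
    if not 0 <= coarse_col < grid.n_coarse_cols:
        raise IndexError(f"coarse_col {coarse_col} out of range")
    return (
        slice(coarse_row * f, (coarse_row + 1) * f),
        slice(coarse_col * f, (coarse_col + 1) * f),
    )
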