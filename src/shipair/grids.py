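"""Regular lon/lat grids with cosine-latitude area weighting.

Everything downstream (emissions, concentrations, burdens, forcing) lives on a
single :class:`WorldGrid`. Cell membership is half-open, ``[lower, upper)`` in
both longitude and latitude, so each point belongs to exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_M = 6.371e6
M_PER_DEGREE = 2 * np.pi * EARTH_RADIUS_M / 360.0  # ~111.2 km


class ConfigurationError(ValueError):
    """Raised for invalid grid or scenario configuration."""


@dataclass(frozen=True)
class WorldGrid:
    """A regular longitude/latitude grid.

    Parameters are the lower-left corner, the (square, in degrees) cell size
    and the cell counts. Arrays indexed by this grid are shaped
    ``(n_lat, n_lon)`` with latitude as the leading axis.
    """

    lon_min: float
    lat_min: float
    cell_size: float
    n_lon: int
    n_lat: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")
        if self.n_lon < 1 or self.n_lat < 1:
            raise ConfigurationError("grid must contain at least one cell")
        if self.lat_min < -90 or self.lat_max > 90:
            raise ConfigurationError("latitude bounds outside [-90, 90]")
        if self.lon_min < -180 or self.lon_max > 180:
            raise ConfigurationError("longitude bounds outside [-180, 180]")

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.cell_size * self.n_lon

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.cell_size * self.n_lat

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    @property
    def lon_centers(self) -> np.ndarray:
        return self.lon_min + self.cell_size * (np.arange(self.n_lon) + 0.5)

    @property
    def lat_centers(self) -> np.ndarray:
        return self.lat_min + self.cell_size * (np.arange(self.n_lat) + 0.5)

    def cell_areas(self) -> np.ndarray:
        """Cell areas in m**2, shaped (n_lat, n_lon), cosine-latitude weighted."""
        dy = self.cell_size * M_PER_DEGREE
        dx = self.cell_size * M_PER_DEGREE * np.cos(np.deg2rad(self.lat_centers))
        areas = np.outer(dx * dy, np.ones(self.n_lon))
        if np.any(areas <= 0):
            raise ConfigurationError("non-positive cell area; check latitude bounds")
        return areas

    def area_weights(self) -> np.ndarray:
        """Normalised area weights (sum to 1) for global averaging."""
        a = self.cell_areas()
        return a / a.sum()

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon < self.lon_max)
            & (lat >= self.lat_min)
            & (lat < self.lat_max)
        )

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the containing cell. Caller must ensure containment."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.lon_min) / self.cell_size).astype(int)
        row = np.floor((lat - self.lat_min) / self.cell_size).astype(int)
        # points infinitesimally below the upper bound can round up in the
        # division; clamp so contained points always index a valid cell
        return np.clip(row, 0, self.n_lat - 1), np.clip(col, 0, self.n_lon - 1)

    def pairwise_distances_m(self) -> np.ndarray:
        """(n_cells, n_cells) great-circle-approximate distances between cell centres.

        Uses the equirectangular approximation (dx scaled by cos of the mean
        latitude of the pair), adequate for the desk-scale domains this
        package targets.
        """
        lon = self.lon_centers
        lat = self.lat_centers
        LON, LAT = np.meshgrid(lon, lat)
        lonf = LON.ravel()
        latf = LAT.ravel()
        dlat = latf[:, None] - latf[None, :]
        dlon = lonf[:, None] - lonf[None, :]
        coslat = np.cos(np.deg2rad(0.5 * (latf[:, None] + latf[None, :])))
        return M_PER_DEGREE * np.hypot(dlat, dlon * coslat)
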