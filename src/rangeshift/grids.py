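"""Nested grid geometry and plain-text raster I/O.

All coordinates are planar kilometres on a national-grid-like plane
(easting, northing).  Three grains are used throughout:

* hectad — 10 km x 10 km squares, the grain of range-shift analysis;
* focal (1-ha) pixels — 100 m, the grain of precise species records;
* land-cover pixels — 25 m, the grain of the habitat map.

Arrays are indexed ``[row, col]`` with row 0 the *southernmost* row, so
``array[iy, ix]`` sits at increasing northing for increasing ``iy``.
ESRI ASCII grids store rows north-to-south; the I/O helpers flip
accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

HECTAD_KM = 10.0
HA_KM = 0.1
LC_KM = 0.025
HA_PER_HECTAD = 100  # 1-ha pixels along one hectad edge
LC_PER_HA = 4  # 25 m pixels along one 1-ha pixel edge
COARSE_KM = 5.0  # grain of the input climate grids


@dataclass(frozen=True)
class GridSpec:
    """Rectangular study region defined on the hectad lattice.

    The hectad grid exactly tiles the region; every 1-ha pixel nests in
    exactly one hectad and every 25 m pixel in exactly one 1-ha pixel.

    Parameters
    ----------
    origin_easting_km, origin_northing_km
        South-west corner of the region, km.
    n_hectads_east, n_hectads_north
        Extent in hectads; must be positive.
    """

    origin_easting_km: float
    origin_northing_km: float
    n_hectads_east: int
    n_hectads_north: int

    def __post_init__(self) -> None:
        if self.n_hectads_east <= 0 or self.n_hectads_north <= 0:
            raise ValueError("grid dimensions must be positive")

    # --- shapes -------------------------------------------------------
    @property
    def hectad_shape(self) -> tuple[int, int]:
        return (self.n_hectads_north, self.n_hectads_east)

    @property
    def n_hectads(self) -> int:
        return self.n_hectads_north * self.n_hectads_east

    @property
    def ha_shape(self) -> tuple[int, int]:
        return (self.n_hectads_north * HA_PER_HECTAD, self.n_hectads_east * HA_PER_HECTAD)

    @property
    def lc_shape(self) -> tuple[int, int]:
        ny, nx = self.ha_shape
        return (ny * LC_PER_HA, nx * LC_PER_HA)

    @property
    def coarse_shape(self) -> tuple[int, int]:
        """Shape of the 5 km climate grid covering the region."""
        return (
            int(self.n_hectads_north * HECTAD_KM / COARSE_KM),
            int(self.n_hectads_east * HECTAD_KM / COARSE_KM),
        )

    @property
    def north_edge_km(self) -> float:
        return self.origin_northing_km + self.n_hectads_north * HECTAD_KM

    @property
    def east_edge_km(self) -> float:
        return self.origin_easting_km + self.n_hectads_east * HECTAD_KM

    # --- centre coordinates ------------------------------------------
    def hectad_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(northings, eastings) of hectad centres, each shaped like the hectad grid."""
        iy, ix = np.mgrid[0 : self.n_hectads_north, 0 : self.n_hectads_east]
        n = self.origin_northing_km + (iy + 0.5) * HECTAD_KM
        e = self.origin_easting_km + (ix + 0.5) * HECTAD_KM
        return n, e

    def hectad_centre(self, iy: int, ix: int) -> tuple[float, float]:
        return (
            self.origin_northing_km + (iy + 0.5) * HECTAD_KM,
            self.origin_easting_km + (ix + 0.5) * HECTAD_KM,
        )

    def ha_centres_1d(self) -> tuple[np.ndarray, np.ndarray]:
        """1-d northings (per row) and eastings (per col) of 1-ha pixel centres."""
        ny, nx = self.ha_shape
        n = self.origin_northing_km + (np.arange(ny) + 0.5) * HA_KM
        e = self.origin_easting_km + (np.arange(nx) + 0.5) * HA_KM
        return n, e

    def coarse_centres_1d(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.coarse_shape
        n = self.origin_northing_km + (np.arange(ny) + 0.5) * COARSE_KM
        e = self.origin_easting_km + (np.arange(nx) + 0.5) * COARSE_KM
        return n, e

    # --- index mapping ------------------------------------------------
    def hectad_id(self, iy, ix):
        """Deterministic scalar id for a hectad: row-major from the SW corner."""
        return np.asarray(iy) * self.n_hectads_east + np.asarray(ix)

    def hectad_of_point(self, easting_km, northing_km):
        """(iy, ix) hectad indices containing planar points; errors off-region."""
        ix = np.floor((np.asarray(easting_km) - self.origin_easting_km) / HECTAD_KM).astype(int)
        iy = np.floor((np.asarray(northing_km) - self.origin_northing_km) / HECTAD_KM).astype(int)
        if np.any((ix < 0) | (ix >= self.n_hectads_east) | (iy < 0) | (iy >= self.n_hectads_north)):
            raise ValueError("point outside the study region")
        return iy, ix

    def ha_of_point(self, easting_km, northing_km):
        """(iy, ix) 1-ha pixel indices containing planar points."""
        ix = np.floor((np.asarray(easting_km) - self.origin_easting_km) / HA_KM).astype(int)
        iy = np.floor((np.asarray(northing_km) - self.origin_northing_km) / HA_KM).astype(int)
        ny, nx = self.ha_shape
        if np.any((ix < 0) | (ix >= nx) | (iy < 0) | (iy >= ny)):
            raise ValueError("point outside the study region")
        return iy, ix


def write_ascii_grid(
    path: str | Path,
    array: np.ndarray,
    xllcorner: float,
    yllcorner: float,
    cellsize: float,
    nodata: float = -9999,
) -> None:
    """Write a single-band raster as an ESRI ASCII grid.

    ``array`` follows the package convention (row 0 = south); the file
    is written north-to-south as the format requires.
    """
    a = np.asarray(array)
    header = (
        f"ncols {a.shape[1]}\n"
        f"nrows {a.shape[0]}\n"
        f"xllcorner {xllcorner}\n"
        f"yllcorner {yllcorner}\n"
        f"cellsize {cellsize}\n"
        f"NODATA_value {nodata}\n"
    )
    fmt = "%d" if np.issubdtype(a.dtype, np.integer) else "%.6g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, a[::-1], fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array row 0 = south, header dict)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)[::-1]
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("raster shape does not match header")
    return data, header
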