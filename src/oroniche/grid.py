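"""Georeferenced raster grids.

A :class:`Grid` is the universal carrier for every gridded quantity in the
package: elevation, climate surfaces, categorical land cover, suitability
maps, boolean masks and bias weights.  It is a thin wrapper around a 2-D
numpy array plus the minimal georeferencing needed for planar or geographic
analysis: cell size, lower-left origin and a nodata convention (NaN for
float grids, a sentinel for integer grids).

Row 0 is the *top* row of the map, as in ESRI ASCII grids; the y coordinate
of a cell centre therefore decreases with row index.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Grid",
    "OronicheError",
    "ConfigurationError",
    "AlignmentError",
    "GeometryError",
    "SamplingError",
    "PipelineError",
    "EARTH_RADIUS_M",
]

#: Mean Earth radius used for all great-circle distances (m).
EARTH_RADIUS_M = 6_371_000.0

#: Nodata sentinel written to / recognised in ESRI ASCII files.
ASCII_NODATA = -9999.0


class OronicheError(Exception):
    """Base class for package errors."""


class ConfigurationError(OronicheError):
    """Invalid configuration value."""


class AlignmentError(OronicheError):
    """Grids that must share shape/cell size/origin do not."""


class GeometryError(OronicheError):
    """Invalid or empty geometry input."""


class SamplingError(OronicheError):
    """A sampling operation has no valid support."""


class PipelineError(OronicheError):
    """A pipeline stage failed; message names the stage."""


@dataclass
class Grid:
    """A 2-D raster with cell size, lower-left origin and nodata mask.

    Parameters
    ----------
    values
        2-D array.  Float grids use NaN for nodata; integer/bool grids are
        assumed fully valid unless ``nodata_value`` is set.
    cell_size
        Edge length of a (square) cell — metres for planar grids, degrees
        for geographic ones.
    origin
        ``(x, y)`` of the lower-left *corner* of the grid.
    geographic
        If True, coordinates are lon/lat degrees and distance computations
        use great circles.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    geographic: bool = False
    nodata_value: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ConfigurationError("Grid values must be 2-D")
        if self.cell_size <= 0:
            raise ConfigurationError("cell_size must be positive")

    # -- basic properties -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        if np.issubdtype(self.values.dtype, np.floating):
            valid = np.isfinite(self.values)
            if self.nodata_value is not None:
                valid &= self.values != self.nodata_value
            return valid
        if self.nodata_value is not None:
            return self.values != self.nodata_value
        return np.ones(self.shape, dtype=bool)

    # -- georeferencing ---------------------------------------------------
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x, y)`` 2-D arrays of cell-centre coordinates."""
        x0, y0 = self.origin
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = x0 + (cols + 0.5) * self.cell_size
        y = y0 + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def xy_of(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell-centre coordinates of the given row/col indices."""
        x0, y0 = self.origin
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        x = x0 + (cols + 0.5) * self.cell_size
        y = y0 + (self.n_rows - rows - 0.5) * self.cell_size
        return x, y

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing the given points.

        Points outside the grid extent are clipped to the border cells.
        """
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        row = (self.n_rows - 1 - np.floor((np.asarray(y) - y0) / self.cell_size)).astype(int)
        return np.clip(row, 0, self.n_rows - 1), np.clip(col, 0, self.n_cols - 1)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x0, y0 = self.origin
        x = np.asarray(x)
        y = np.asarray(y)
        return (
            (x >= x0)
            & (x <= x0 + self.n_cols * self.cell_size)
            & (y >= y0)
            & (y <= y0 + self.n_rows * self.cell_size)
        )

    # -- alignment --------------------------------------------------------
    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
            and self.geographic == other.geographic
        )

    def require_aligned(self, other: "Grid", what: str = "grids") -> None:
        if not self.aligned_with(other):
            raise AlignmentError(f"{what} are not aligned (shape/cell size/origin differ)")

    def like(self, values: np.ndarray) -> "Grid":
        """A new grid sharing this grid's georeferencing."""
        return replace(self, values=np.asarray(values), nodata_value=None)

    def copy(self) -> "Grid":
        return replace(self, values=self.values.copy())

    # -- I/O ---------------------------------------------------------------
    def write_ascii(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid (NaN → -9999)."""
        vals = np.asarray(self.values, dtype=float).copy()
        vals[~self.mask] = ASCII_NODATA
        buf = io.StringIO()
        buf.write(f"ncols {self.n_cols}\n")
        buf.write(f"nrows {self.n_rows}\n")
        buf.write(f"xllcorner {self.origin[0]:.6f}\n")
        buf.write(f"yllcorner {self.origin[1]:.6f}\n")
        buf.write(f"cellsize {self.cell_size:.6f}\n")
        buf.write(f"NODATA_value {ASCII_NODATA:g}\n")
        np.savetxt(buf, vals, fmt="%.6g")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def read_ascii(cls, path: str | Path, geographic: bool = False) -> "Grid":
        """Read an ESRI ASCII grid; nodata cells become NaN."""
        text = Path(path).read_text().splitlines()
        header: dict[str, float] = {}
        i = 0
        while i < len(text):
            parts = text[i].split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                i += 1
            else:
                break
        vals = np.loadtxt(io.StringIO("\n".join(text[i:])), ndmin=2)
        nodata = header.get("nodata_value", ASCII_NODATA)
        vals[vals == nodata] = np.nan
        return cls(
            values=vals,
            cell_size=header["cellsize"],
            origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
            geographic=geographic,
        )


def pairwise_distance(
    x1: np.ndarray, y1: np.ndarray, x2: np.ndarray, y2: np.ndarray, geographic: bool = False
) -> np.ndarray:
    """Distance matrix between two point sets (m for planar, m via great
    circle for geographic lon/lat inputs)."""
    x1 = np.atleast_1d(np.asarray(x1, dtype=float))
    y1 = np.atleast_1d(np.asarray(y1, dtype=float))
    x2 = np.atleast_1d(np.asarray(x2, dtype=float))
    y2 = np.atleast_1d(np.asarray(y2, dtype=float))
    if not geographic:
        return np.hypot(x1[:, None] - x2[None, :], y1[:, None] - y2[None, :])
    lon1, lat1 = np.radians(x1), np.radians(y1)
    lon2, lat2 = np.radians(x2), np.radians(y2)
    dlat = lat1[:, None] - lat2[None, :]
    dlon = lon1[:, None] - lon2[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1)[:, None] * np.cos(lat2)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
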