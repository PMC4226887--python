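"""Topographic and habitat predictors derived from elevation and land cover.

The central derivative is *abruptness* (ABR): the local relief of the
landscape, computed per cell as the maximum elevation difference (window
max − window min) over a circular neighbourhood of fixed radius (default
5 km).  Abruptness summarises the elevation range a mobile animal can
reach within its home range, and in mountain systems it separates steep
massifs from high plateaus in a way raw elevation cannot.

Also provided: slope and aspect from the standard Horn 3×3 stencil,
Euclidean distance-to-class rasters from categorical land cover, and
land-cover reclassification to a reduced category set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import (
    AlignmentError,
    ConfigurationError,
    EARTH_RADIUS_M,
    Grid,
    OronicheError,
)

__all__ = [
    "PredictorStack",
    "abruptness",
    "slope",
    "aspect",
    "distance_to_class",
    "reclassify_landcover",
    "MappingError",
    "VARIABLE_GROUPS",
    "variable_group",
]

#: Predictor code → variable type, following the standard two-scale menu:
#: climatic bioclim surfaces (B*), topographic derivatives, and
#: habitat/land-cover variables.
VARIABLE_GROUPS: dict[str, str] = {
    "ABR": "topographic",
    "ELEV": "topographic",
    "SLO": "topographic",
    "ORI": "topographic",
    "B4": "climatic",
    "B8": "climatic",
    "B10": "climatic",
    "B12": "climatic",
    "B15": "climatic",
    "B17": "climatic",
    "LAND": "habitat",
    "DIS-ROCK": "habitat",
    "DIS-FOREST": "habitat",
    "DIS-URBAN": "habitat",
}


def variable_group(name: str) -> str:
    """Variable type ('climatic' | 'topographic' | 'habitat') for a code.

    Unknown codes default by prefix: B* → climatic, DIS-* → habitat,
    otherwise topographic.
    """
    if name in VARIABLE_GROUPS:
        return VARIABLE_GROUPS[name]
    if name.startswith("B") and name[1:].isdigit():
        return "climatic"
    if name.startswith("DIS-"):
        return "habitat"
    if name in {"LAND", "LANDCOVER"}:
        return "habitat"
    return "topographic"


class MappingError(OronicheError):
    """A land-cover code has no entry in the reclassification table."""


@dataclass
class PredictorStack:
    """Named, aligned predictor grids plus categorical metadata."""

    grids: dict[str, Grid]
    categorical: set[str] = field(default_factory=set)
    categories: dict[str, dict[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.grids)
        if names:
            ref = self.grids[names[0]]
            for n in names[1:]:
                if not ref.aligned_with(self.grids[n]):
                    raise AlignmentError(f"predictor {n!r} not aligned with {names[0]!r}")

    @property
    def names(self) -> list[str]:
        return list(self.grids)

    @property
    def reference(self) -> Grid:
        return next(iter(self.grids.values()))

    @property
    def mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        m = np.ones(self.reference.shape, dtype=bool)
        for g in self.grids.values():
            m &= g.mask
        return m

    def subset(self, names: list[str]) -> "PredictorStack":
        missing = [n for n in names if n not in self.grids]
        if missing:
            raise ConfigurationError(f"unknown predictors: {missing}")
        return PredictorStack(
            grids={n: self.grids[n] for n in names},
            categorical={n for n in names if n in self.categorical},
            categories={n: self.categories[n] for n in names if n in self.categories},
        )

    def sample(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_points, n_variables) matrix of values at the given cells."""
        return np.column_stack(
            [np.asarray(self.grids[n].values, dtype=float)[rows, cols] for n in self.names]
        )

    def write(self, directory) -> None:
        """Write one ESRI ASCII grid per variable plus a manifest."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        lines = []
        for n, g in self.grids.items():
            fname = f"{n}.asc"
            g.write_ascii(d / fname)
            kind = "categorical" if n in self.categorical else "continuous"
            lines.append(f"{n}\t{fname}\t{kind}")
        (d / "manifest.tsv").write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, directory, geographic: bool = False) -> "PredictorStack":
        from pathlib import Path

        d = Path(directory)
        grids: dict[str, Grid] = {}
        categorical: set[str] = set()
        for line in (d / "manifest.tsv").read_text().splitlines():
            if not line.strip():
                continue
            name, fname, kind = line.split("\t")
            grids[name] = Grid.read_ascii(d / fname, geographic=geographic)
            if kind == "categorical":
                categorical.add(name)
        return cls(grids=grids, categorical=categorical)


def _disk_footprint(radius: float, cell_size: float) -> np.ndarray:
    r_cells = int(np.floor(radius / cell_size))
    offsets = np.arange(-r_cells, r_cells + 1)
    dy, dx = np.meshgrid(offsets, offsets, indexing="ij")
    # cell-centre to cell-centre distance, focal cell included
    return np.hypot(dy, dx) * cell_size <= radius + 1e-9


def abruptness(elev: Grid, radius: float = 5000.0) -> Grid:
    """Local relief: window max − window min of elevation within ``radius``.

    The neighbourhood is circular (a buffer of ``radius`` around the focal
    cell centre, by cell-centre distance, focal cell included).  Nodata
    cells are ignored; a cell whose whole neighbourhood is nodata gets
    nodata.  The result is translation invariant in elevation and
    non-negative everywhere.
    """
    if radius < elev.cell_size:
        raise ConfigurationError("abruptness radius must be >= cell size")
    fp = _disk_footprint(radius, elev.cell_size)
    vals = np.asarray(elev.values, dtype=float)
    valid = elev.mask
    hi = np.where(valid, vals, -np.inf)
    lo = np.where(valid, vals, np.inf)
    wmax = ndimage.maximum_filter(hi, footprint=fp, mode="constant", cval=-np.inf)
    wmin = ndimage.minimum_filter(lo, footprint=fp, mode="constant", cval=np.inf)
    out = wmax - wmin
    out[~np.isfinite(wmax) | ~np.isfinite(wmin)] = np.nan
    return elev.like(out)


def _horn_gradients(elev: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Horn (3×3 average-gradient) dz/dx (east) and dz/dy (north), m/m."""
    if elev.n_rows < 3 or elev.n_cols < 3:
        raise ConfigurationError("slope/aspect require a grid of at least 3x3 cells")
    z = np.asarray(elev.values, dtype=float)
    if elev.geographic:
        # metres per degree at the grid's mean latitude
        _, ycent = elev.cell_centers()
        lat = np.radians(ycent.mean())
        dx_m = elev.cell_size * np.pi / 180.0 * EARTH_RADIUS_M * np.cos(lat)
        dy_m = elev.cell_size * np.pi / 180.0 * EARTH_RADIUS_M
    else:
        dx_m = dy_m = elev.cell_size
    gx = np.full_like(z, np.nan)
    gy = np.full_like(z, np.nan)
    c = z[1:-1, 1:-1]  # noqa: F841 (clarity)
    # neighbours: z[r-1,c-1] .. z[r+1,c+1]
    a, b_, cc = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    gx[1:-1, 1:-1] = ((cc + 2 * f + i) - (a + 2 * d + g)) / (8 * dx_m)
    gy[1:-1, 1:-1] = ((a + 2 * b_ + cc) - (g + 2 * h + i)) / (8 * dy_m)
    invalid = ~elev.mask
    # any nodata in the 3x3 window invalidates the cell
    bad = ndimage.maximum_filter(invalid.astype(np.uint8), size=3, mode="constant", cval=1) > 0
    gx[bad] = np.nan
    gy[bad] = np.nan
    return gx, gy


def slope(elev: Grid) -> Grid:
    """Slope in degrees from the Horn 3×3 average gradient (border = nodata)."""
    gx, gy = _horn_gradients(elev)
    return elev.like(np.degrees(np.arctan(np.hypot(gx, gy))))


def aspect(elev: Grid) -> Grid:
    """Aspect: compass direction of the upslope gradient, degrees clockwise
    from north in [0, 360).  Flat cells (zero gradient) get nodata."""
    gx, gy = _horn_gradients(elev)
    asp = np.degrees(np.arctan2(gx, gy)) % 360.0
    asp[(gx == 0) & (gy == 0)] = np.nan
    return elev.like(asp)


def distance_to_class(landcover: Grid, class_label: int) -> Grid:
    """Euclidean distance from every cell centre to the nearest cell centre
    of the given land-cover class (0 on cells of the class itself).

    Planar grids use an exact Euclidean distance transform; geographic
    grids use great-circle distance via nearest-neighbour search on the
    unit sphere.  If the class is absent the result is all-infinite and a
    warning is issued.
    """
    is_class = (np.asarray(landcover.values) == class_label) & landcover.mask
    if not is_class.any():
        warnings.warn(f"land-cover class {class_label} absent; distances are infinite",
                      stacklevel=2)
        return landcover.like(np.full(landcover.shape, np.inf))
    if not landcover.geographic:
        dist = ndimage.distance_transform_edt(~is_class, sampling=landcover.cell_size)
        return landcover.like(np.asarray(dist, dtype=float))
    from scipy.spatial import cKDTree

    x, y = landcover.cell_centers()
    lon, lat = np.radians(x.ravel()), np.radians(y.ravel())
    xyz = np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )
    tree = cKDTree(xyz[is_class.ravel()])
    chord, _ = tree.query(xyz)
    dist = 2 * EARTH_RADIUS_M * np.arcsin(np.clip(chord / 2, 0, 1))
    return landcover.like(dist.reshape(landcover.shape))


def reclassify_landcover(raw: Grid, mapping: dict[int, int]) -> Grid:
    """Map raw land-cover codes to the reduced category set.

    Every code present in the (valid) grid must appear in ``mapping``;
    unmapped codes raise :class:`MappingError` listing the offenders.
    """
    vals = np.asarray(raw.values)
    valid = raw.mask
    present = set(np.unique(vals[valid]).astype(int).tolist())
    unmapped = sorted(present - set(mapping))
    if unmapped:
        raise MappingError(f"unmapped land-cover codes: {unmapped}")
    out = np.full(raw.shape, -1, dtype=int)
    for src, dst in mapping.items():
        out[(vals == src) & valid] = dst
    result = raw.like(out)
    result.nodata_value = -1
    return result
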