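"""Range-overlap similarity and palealpine classification.

Quantifies how closely the geographic range of each comparison species
matches a focal species' range, using the Sørensen Similarity Index on
rasterized range masks,

    SSI(A, B) = 2|A ∩ B| / (|A| + |B|),

and a corrected index cSSI = min(1, SSI / e) where the error factor
``e ∈ (0, 1]`` quantifies the uncertainty of the reference range layers
(estimated by comparing two independent range maps of the focal species
itself).  Species whose cSSI reaches a resemblance threshold (default
0.60) are classified as sharing the focal distribution pattern —
"palealpine" in the mountain-vertebrate context this package targets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape

from .grid import ConfigurationError, GeometryError, Grid

__all__ = [
    "RangeMask",
    "OverlapResult",
    "rasterize_range",
    "sorensen_similarity",
    "corrected_ssi",
    "classify_palealpine",
    "overlap_summary",
    "compute_overlaps",
    "read_ranges_geojson",
    "write_ranges_geojson",
    "results_to_frame",
    "plot_overlap_ranking",
    "DEFAULT_PALEALPINE_THRESHOLD",
]

#: cSSI at or above this marks a range as sharing the focal pattern.
DEFAULT_PALEALPINE_THRESHOLD = 0.60


@dataclass
class RangeMask:
    """A species' range as a boolean raster aligned to a reference grid."""

    grid: Grid
    species_id: str = ""

    def __post_init__(self) -> None:
        self.grid = Grid(
            values=np.asarray(self.grid.values, dtype=bool),
            cell_size=self.grid.cell_size,
            origin=self.grid.origin,
            geographic=self.grid.geographic,
        )

    @property
    def n_cells(self) -> int:
        return int(self.grid.values.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_cells == 0


@dataclass
class OverlapResult:
    species_id: str
    ssi: float
    cssi: float
    is_palealpine: bool = False


def rasterize_range(polygon, reference: Grid, species_id: str = "") -> RangeMask:
    """Rasterize a (multi)polygon onto the reference grid.

    A cell is part of the range iff its centre lies inside the polygon —
    no partial-cell weighting, so counts are exactly reproducible.  A
    valid polygon too small to capture any cell centre yields an empty
    mask and a warning.
    """
    if polygon is None or getattr(polygon, "is_empty", True):
        raise GeometryError(f"empty or invalid polygon for species {species_id!r}")
    x, y = reference.cell_centers()
    inside = shapely.contains_xy(polygon, x.ravel(), y.ravel()).reshape(reference.shape)
    mask = RangeMask(grid=reference.like(inside), species_id=species_id)
    if mask.is_empty:
        warnings.warn(
            f"polygon for {species_id!r} contains no cell centre; mask is empty",
            stacklevel=2,
        )
    return mask


def sorensen_similarity(a: RangeMask, b: RangeMask) -> float:
    """Sørensen Similarity Index 2|A∩B| / (|A|+|B|) on aligned masks."""
    a.grid.require_aligned(b.grid, "range masks")
    na, nb = a.n_cells, b.n_cells
    if na + nb == 0:
        raise GeometryError("similarity undefined: both range masks are empty")
    inter = int(np.logical_and(a.grid.values, b.grid.values).sum())
    return 2.0 * inter / (na + nb)


def corrected_ssi(ssi: float, error_factor: float) -> float:
    """Corrected SSI: ssi / error_factor, capped at 1.

    ``error_factor`` is the SSI between two independent range maps of the
    same (focal) species; dividing by it rescales so that a comparison as
    similar as the focal self-comparison scores 1.
    """
    if error_factor <= 0 or error_factor > 1:
        raise ConfigurationError("error_factor must be in (0, 1]")
    if not 0 <= ssi <= 1:
        raise ConfigurationError("ssi must be in [0, 1]")
    return min(1.0, ssi / error_factor)


def classify_palealpine(
    results: list[OverlapResult], threshold: float = DEFAULT_PALEALPINE_THRESHOLD
) -> list[OverlapResult]:
    """Flag results with cssi >= threshold (inclusive) and rank them.

    Returns a new list sorted by descending cssi, ties broken by
    species_id.
    """
    out = [
        OverlapResult(r.species_id, r.ssi, r.cssi, bool(r.cssi >= threshold))
        for r in results
    ]
    out.sort(key=lambda r: (-r.cssi, r.species_id))
    return out


def overlap_summary(groups: dict[str, list[float]]) -> pd.DataFrame:
    """Mean ± sample SD of cSSI per taxon group.

    Single-member groups report SD as missing; empty groups report both
    as missing.
    """
    rows = []
    for name, values in groups.items():
        values = list(values)
        if not values:
            rows.append({"group": name, "n": 0, "mean": np.nan, "sd": np.nan})
        elif len(values) == 1:
            rows.append({"group": name, "n": 1, "mean": float(values[0]), "sd": np.nan})
        else:
            arr = np.asarray(values, dtype=float)
            rows.append(
                {"group": name, "n": len(values), "mean": float(arr.mean()),
                 "sd": float(arr.std(ddof=1))}
            )
    return pd.DataFrame(rows)


def compute_overlaps(
    focal: RangeMask,
    others: list[RangeMask],
    error_factor: float,
    threshold: float = DEFAULT_PALEALPINE_THRESHOLD,
) -> list[OverlapResult]:
    """SSI and cSSI of every comparison range against the focal range."""
    results = []
    for other in others:
        ssi = sorensen_similarity(focal, other) if not other.is_empty else 0.0
        results.append(OverlapResult(other.species_id, ssi, corrected_ssi(ssi, error_factor)))
    return classify_palealpine(results, threshold)


# -- I/O and presentation -------------------------------------------------

def read_ranges_geojson(path: str | Path) -> dict[str, object]:
    """Read a GeoJSON FeatureCollection into {species: shapely geometry}.

    The species identifier is taken from the feature property ``species``.
    """
    data = json.loads(Path(path).read_text())
    out: dict[str, object] = {}
    for feat in data.get("features", []):
        sp = feat.get("properties", {}).get("species", f"feature_{len(out)}")
        out[sp] = shapely_shape(feat["geometry"])
    return out


def write_ranges_geojson(geoms: dict[str, object], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"species": sp},
            "geometry": json.loads(shapely.to_geojson(geom)),
        }
        for sp, geom in geoms.items()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def results_to_frame(results: list[OverlapResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"species": r.species_id, "ssi": r.ssi, "cssi": r.cssi,
             "is_palealpine": r.is_palealpine}
            for r in results
        ]
    )


def plot_overlap_ranking(results: list[OverlapResult], path: str | Path,
                         threshold: float = DEFAULT_PALEALPINE_THRESHOLD) -> None:
    """Ranked cSSI bar chart (species sorted by decreasing similarity)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranked = classify_palealpine(results, threshold)
    fig, ax = plt.subplots(figsize=(max(4, 0.25 * len(ranked)), 4))
    ax.bar(range(len(ranked)), [r.cssi for r in ranked],
           color=["tab:red" if r.is_palealpine else "tab:gray" for r in ranked])
    ax.axhline(threshold, color="k", ls="--", lw=0.8)
    ax.set_ylabel("cSSI")
    ax.set_xticks(range(len(ranked)))
    ax.set_xticklabels([r.species_id for r in ranked], rotation=90, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
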