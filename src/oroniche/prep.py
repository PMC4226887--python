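"""Occurrence-record preparation and predictor screening.

Implements the record-quality filters applied before presence-background
modelling (verification, location uncertainty, spatial pseudoreplication,
source-type and geographic homogeneity), the sampling-bias grid used to
correct uneven survey effort, the calibration area (union of buffers
around presences from which background cells are drawn) and the
Spearman-correlation screen that removes redundant predictors.

Occurrence sets are plain pandas DataFrames with the columns
``species, lon, lat, uncertainty_m, source_type, region, verified``
(coordinates in metres on planar grids, lon/lat degrees on geographic
ones).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .grid import (
    ConfigurationError,
    EARTH_RADIUS_M,
    Grid,
    PipelineError,
    pairwise_distance,
)
from .terrain import PredictorStack

__all__ = [
    "OCCURRENCE_COLUMNS",
    "read_occurrences",
    "write_occurrences",
    "filter_records",
    "homogenize_strata",
    "thin_spatial",
    "thin_one_per_cell",
    "BiasGrid",
    "build_bias_grid",
    "calibration_area",
    "sample_background",
    "correlation_screen",
]

OCCURRENCE_COLUMNS = ["species", "lon", "lat", "uncertainty_m", "source_type",
                      "region", "verified"]


def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"occurrence CSV missing columns: {missing}")
    df["verified"] = df["verified"].astype(bool)
    return df


def write_occurrences(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False, columns=OCCURRENCE_COLUMNS)


def filter_records(
    records: pd.DataFrame,
    require_verified: bool = True,
    max_uncertainty: float = 1000.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the verification and location-uncertainty filters.

    Returns the surviving records and a report of counts removed per
    criterion (a record failing both is counted under both).  An empty
    result aborts the pipeline.
    """
    unverified = ~records["verified"].astype(bool) if require_verified else pd.Series(
        False, index=records.index
    )
    imprecise = records["uncertainty_m"] > max_uncertainty
    kept = records[~unverified & ~imprecise].reset_index(drop=True)
    report = {
        "input": len(records),
        "removed_unverified": int(unverified.sum()),
        "removed_uncertain": int(imprecise.sum()),
        "kept": len(kept),
    }
    if kept.empty:
        raise PipelineError("record filtering removed every record")
    return kept, report


def homogenize_strata(
    records: pd.DataFrame, column: str, max_ratio: float = 1.5, seed: int = 0
) -> pd.DataFrame:
    """Down-sample over-represented strata of ``column`` (e.g. source_type
    or region) until no stratum exceeds ``max_ratio`` times the smallest.

    This is the package's quantitative reading of the source-type and
    geographic homogeneity filters; the ratio is explicit configuration.
    """
    if max_ratio < 1:
        raise ConfigurationError("max_ratio must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = records.groupby(column).size()
    if sizes.empty:
        return records
    target = int(np.floor(max_ratio * sizes.min()))
    pieces = []
    for value, group in records.groupby(column, sort=True):
        if len(group) > target:
            idx = rng.choice(len(group), size=target, replace=False)
            group = group.iloc[np.sort(idx)]
        pieces.append(group)
    return pd.concat(pieces).sort_index().reset_index(drop=True)


def thin_spatial(
    records: pd.DataFrame,
    min_distance: float = 10_000.0,
    seed: int = 0,
    geographic: bool = False,
    order: str = "random",
) -> pd.DataFrame:
    """Greedy spatial thinning: visit records in seeded random order (or
    input order with ``order='given'``) and keep each one iff it lies at
    least ``min_distance`` from every record already kept.

    The output is maximal for its insertion order: every removed record
    is within ``min_distance`` of some kept record.
    """
    if min_distance <= 0:
        raise ConfigurationError("min_distance must be positive")
    n = len(records)
    if n <= 1:
        return records.reset_index(drop=True)
    if order == "random":
        visit = np.random.default_rng(seed).permutation(n)
    elif order == "given":
        visit = np.arange(n)
    else:
        raise ConfigurationError("order must be 'random' or 'given'")
    x = records["lon"].to_numpy(dtype=float)
    y = records["lat"].to_numpy(dtype=float)
    kept: list[int] = []
    for i in visit:
        if not kept:
            kept.append(i)
            continue
        d = pairwise_distance(x[[i]], y[[i]], x[kept], y[kept], geographic=geographic)
        if d.min() >= min_distance:
            kept.append(i)
    kept_sorted = sorted(kept)
    return records.iloc[kept_sorted].reset_index(drop=True)


def thin_one_per_cell(
    records: pd.DataFrame, reference: Grid, seed: int = 0
) -> pd.DataFrame:
    """Keep at most one record per cell of the reference grid.

    Within a cell the survivor is the first record in seeded random
    order.
    """
    if records.empty:
        return records.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    rows, cols = reference.cell_of(records["lon"].to_numpy(), records["lat"].to_numpy())
    cell_id = rows * reference.n_cols + cols
    visit = rng.permutation(len(records))
    seen: set[int] = set()
    kept: list[int] = []
    for i in visit:
        cid = int(cell_id[i])
        if cid not in seen:
            seen.add(cid)
            kept.append(i)
    return records.iloc[sorted(kept)].reset_index(drop=True)


@dataclass
class BiasGrid:
    """Relative sampling-effort weights; background cells are drawn with
    probability proportional to weight."""

    grid: Grid

    def __post_init__(self) -> None:
        vals = np.asarray(self.grid.values, dtype=float)
        if np.any(vals[self.grid.mask] <= 0):
            raise ConfigurationError("bias weights must be positive on usable cells")


def build_bias_grid(regions: Grid, weights: dict[int, float]) -> BiasGrid:
    """Per-region sampling weights (e.g. {west: 4, east: 1} when western
    survey effort was four-fold the eastern one)."""
    labels = np.asarray(regions.values).astype(int)
    present = set(np.unique(labels[regions.mask]).tolist())
    missing = present - set(weights)
    if missing:
        raise ConfigurationError(f"regions without bias weight: {sorted(missing)}")
    for lab, w in weights.items():
        if w <= 0:
            raise ConfigurationError(f"bias weight for region {lab} must be positive")
    out = np.ones(regions.shape, dtype=float)
    for lab, w in weights.items():
        out[labels == lab] = w
    return BiasGrid(grid=regions.like(out))


def calibration_area(
    records: pd.DataFrame, reference: Grid, buffer_radius: float = 500_000.0
) -> Grid:
    """Boolean grid: cells whose centres lie within ``buffer_radius`` of
    any presence record.  Background points are drawn only from true
    cells."""
    if records.empty:
        raise PipelineError("calibration area requires at least one record")
    if buffer_radius < 0:
        raise ConfigurationError("buffer_radius must be >= 0")
    x, y = reference.cell_centers()
    px = records["lon"].to_numpy(dtype=float)
    py = records["lat"].to_numpy(dtype=float)
    if reference.geographic:
        def to_xyz(lon, lat):
            lon, lat = np.radians(lon), np.radians(lat)
            return np.column_stack(
                [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
            )
        tree = cKDTree(to_xyz(px, py))
        chord, _ = tree.query(to_xyz(x.ravel(), y.ravel()))
        dist = 2 * EARTH_RADIUS_M * np.arcsin(np.clip(chord / 2, 0, 1))
    else:
        tree = cKDTree(np.column_stack([px, py]))
        dist, _ = tree.query(np.column_stack([x.ravel(), y.ravel()]))
    inside = (dist <= buffer_radius).reshape(reference.shape)
    return reference.like(inside)


def sample_background(
    n: int,
    calibration: Grid,
    bias: BiasGrid | None = None,
    valid: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` background cells (with replacement) from the calibration
    area, with probability proportional to the bias weight.

    Returns (rows, cols).  ``valid`` optionally restricts to cells where
    all predictors are defined.
    """
    usable = np.asarray(calibration.values, dtype=bool) & calibration.mask
    if valid is not None:
        usable &= valid
    rows, cols = np.nonzero(usable)
    if len(rows) == 0:
        raise PipelineError("no usable cells to sample background points from")
    if bias is not None:
        calibration.require_aligned(bias.grid, "calibration and bias grids")
        w = np.asarray(bias.grid.values, dtype=float)[rows, cols]
        p = w / w.sum()
    else:
        p = None
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(rows), size=n, p=p, replace=True)
    return rows[draws], cols[draws]


def correlation_screen(
    stack: PredictorStack,
    sample: tuple[np.ndarray, np.ndarray],
    cutoff: float = 0.65,
    priority: list[str] | None = None,
) -> tuple[PredictorStack, list[dict]]:
    """Drop redundant predictors by pairwise Spearman correlation.

    On the screening sample, repeatedly find the highest-|ρ| continuous
    pair exceeding ``cutoff`` and drop its lower-priority member
    (priority = position in ``priority``, earlier = higher ecological
    standing; defaults to stack order).  Categorical variables are not
    screened.  Constant variables (undefined ρ) are dropped with a
    warning.  Returns the surviving stack and a log of drops.
    """
    rows, cols = sample
    if len(rows) < 3:
        raise ConfigurationError("correlation screen needs at least 3 sample cells")
    priority = priority or stack.names
    unknown = [n for n in stack.names if n not in priority]
    if unknown:
        raise ConfigurationError(f"priority list missing variables: {unknown}")
    rank = {name: i for i, name in enumerate(priority)}
    log: list[dict] = []
    continuous = [n for n in stack.names if n not in stack.categorical]
    values = {
        n: np.asarray(stack.grids[n].values, dtype=float)[rows, cols] for n in continuous
    }
    surviving = list(continuous)
    for n in list(surviving):
        v = values[n][np.isfinite(values[n])]
        if v.size == 0 or np.all(v == v[0]):
            warnings.warn(f"predictor {n!r} is constant on the screening sample; dropped",
                          stacklevel=2)
            surviving.remove(n)
            log.append({"dropped": n, "kept": None, "rho": np.nan,
                        "reason": "constant"})
    while True:
        worst = None
        for i, a in enumerate(surviving):
            for b in surviving[i + 1:]:
                ok = np.isfinite(values[a]) & np.isfinite(values[b])
                rho = stats.spearmanr(values[a][ok], values[b][ok]).statistic
                if np.isnan(rho):
                    continue
                if abs(rho) > cutoff and (worst is None or abs(rho) > abs(worst[2])):
                    worst = (a, b, rho)
        if worst is None:
            break
        a, b, rho = worst
        drop, keep = (a, b) if rank[a] > rank[b] else (b, a)
        surviving.remove(drop)
        log.append({"dropped": drop, "kept": keep, "rho": float(rho),
                    "reason": "correlated"})
    final = surviving + [n for n in stack.names if n in stack.categorical]
    final = [n for n in stack.names if n in final]  # preserve stack order
    return stack.subset(final), log
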