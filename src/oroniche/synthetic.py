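"""Synthetic landscapes, climates and virtual species.

Every downstream stage of the package (overlap statistics, terrain
derivatives, occurrence preparation, maximum-entropy modelling and model
selection) is exercisable without external data through this module.  The
generators emulate the statistical structure the analysis assumes:

* a mountain-ridge elevation field — narrow, steep massifs rising from
  flatlands, built as smoothed anisotropic Gaussian bumps along random
  line segments;
* climate surfaces with a within-region elevation lapse plus
  between-region offsets, so the elevation–temperature correlation is
  strong within any one region and weaker across the whole grid (the
  regional vs continental contrast);
* a six-class land cover derived from elevation and temperature by
  threshold rules;
* virtual-species occurrences drawn cell-wise with probability
  proportional to a known suitability function, so parameter-recovery
  experiments have a ground truth;
* overlapping range masks with a controlled overlap fraction, for the
  range-similarity analysis.

All generators are pure functions of (config, seed): identical inputs
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import terrain
from .grid import ConfigurationError, GeometryError, Grid, SamplingError
from .overlap import RangeMask

__all__ = [
    "LandscapeConfig",
    "ClimateConfig",
    "VirtualSpeciesConfig",
    "LandcoverRules",
    "generate_landscape",
    "make_regions",
    "derive_climate",
    "derive_landcover",
    "build_suitability",
    "sample_virtual_occurrences",
    "generate_range_polygons",
    "mask_to_polygon",
    "make_broad_dataset",
    "make_fine_dataset",
    "LC_FOREST", "LC_OPEN", "LC_AGRI", "LC_URBAN", "LC_ICE", "LC_WATER",
    "LANDCOVER_NAMES",
    "FINE_ROCK", "FINE_FOREST", "FINE_URBAN", "FINE_MEADOW",
]

# Broad-scale land-cover classes (the reduced six-category legend).
LC_FOREST, LC_OPEN, LC_AGRI, LC_URBAN, LC_ICE, LC_WATER = 1, 2, 3, 4, 5, 6
LANDCOVER_NAMES = {
    LC_FOREST: "forests",
    LC_OPEN: "open natural areas",
    LC_AGRI: "agricultural areas",
    LC_URBAN: "urban areas",
    LC_ICE: "ice/snow",
    LC_WATER: "water",
}

# Fine-scale land-cover classes (a Corine-like legend with exposed rock).
FINE_ROCK, FINE_FOREST, FINE_URBAN, FINE_MEADOW = 1, 2, 3, 4


@dataclass
class LandscapeConfig:
    """Mountain-ridge elevation field parameters.

    Defaults describe a 200 km × 200 km landscape at 1 km resolution with
    three massifs of ~2.5 km relief above a 200 m baseline — the kind of
    ridge-and-flatland geometry the palealpine biogeography presumes.
    """

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 1000.0  # m
    n_ridges: int = 3
    ridge_amplitude: float = 2500.0  # m
    base_elevation: float = 200.0  # m
    smoothing_scale: float = 6000.0  # m, ridge half-width
    noise_sd: float = 25.0  # m
    seed: int = 0

    def validate(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise ConfigurationError("landscape must be at least 8x8 cells")
        if self.ridge_amplitude < 0 or self.noise_sd < 0:
            raise ConfigurationError("ridge_amplitude and noise_sd must be >= 0")
        if self.cell_size <= 0 or self.smoothing_scale <= 0:
            raise ConfigurationError("cell_size and smoothing_scale must be positive")


@dataclass
class ClimateConfig:
    """Climate-surface parameters.

    Temperature follows an affine elevation lapse within each region,
    ``T = sea_level_temp − lapse_rate·elev/1000 + offset(region) + noise``.
    Distinct region offsets decouple temperature from elevation across the
    whole grid while leaving it tightly coupled within each region.
    Precipitation increases with elevation from ``precip_base``.
    """

    sea_level_temp: float = 22.0  # °C
    lapse_rate: float = 6.5  # °C per km
    region_offsets: dict[int, float] = field(default_factory=lambda: {0: 0.0, 1: 8.0})
    noise_sd: float = 0.5  # °C
    precip_base: float = 700.0  # mm
    precip_elev_slope: float = 300.0  # mm per km of elevation
    seed: int = 0

    def validate(self) -> None:
        if self.lapse_rate <= 0:
            raise ConfigurationError("lapse_rate must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class LandcoverRules:
    """Threshold rules assigning the six broad land-cover classes.

    First matching rule wins: ice/snow below ``ice_temp``; water below
    ``water_elevation``; an ``urban_fraction`` random sprinkle in warm
    lowlands; agricultural where warmer than ``agri_min_temp``; forest
    down to ``forest_min_temp``; open natural areas otherwise (the
    alpine/subalpine belt).
    """

    ice_temp: float = 0.0  # °C
    water_elevation: float = 120.0  # m
    urban_fraction: float = 0.02
    urban_max_elevation: float = 900.0  # m
    urban_min_temp: float = 8.0  # °C
    agri_min_temp: float = 15.0  # °C
    forest_min_temp: float = 6.0  # °C


@dataclass
class VirtualSpeciesConfig:
    """Virtual-species sampling parameters.

    ``response_terms`` define the generating suitability function as a
    product of per-predictor responses; each term is
    ``(predictor_name, shape, params)`` with shape in
    {'linear', 'gaussian', 'threshold'}.
    """

    response_terms: list[tuple[str, str, dict]] = field(default_factory=list)
    n_presences: int = 74
    uncertainty_range: float = 1000.0  # m
    source_types: tuple[str, ...] = ("roost", "capture", "acoustic")
    region_labels: tuple = ()
    verified_fraction: float = 0.95
    species: str = "virtual"
    seed: int = 0

    def validate(self) -> None:
        if self.n_presences < 1:
            raise ConfigurationError("n_presences must be >= 1")
        if not 0 <= self.verified_fraction <= 1:
            raise ConfigurationError("verified_fraction must be in [0, 1]")


def _point_segment_distance(px, py, a, b) -> np.ndarray:
    ax, ay = a
    bx, by = b
    vx, vy = bx - ax, by - ay
    denom = vx * vx + vy * vy
    if denom == 0:
        return np.hypot(px - ax, py - ay)
    t = np.clip(((px - ax) * vx + (py - ay) * vy) / denom, 0.0, 1.0)
    return np.hypot(px - (ax + t * vx), py - (ay + t * vy))


def generate_landscape(cfg: LandscapeConfig) -> Grid:
    """Generate a mountain-ridge elevation grid.

    Each ridge is an elongated Gaussian bump of half-width
    ``smoothing_scale`` along a random line segment; ridges combine by
    maximum (so overlapping massifs do not stack beyond the amplitude)
    and Gaussian noise of sd ``noise_sd`` is added.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ref = Grid(np.zeros((cfg.n_rows, cfg.n_cols)), cell_size=cfg.cell_size)
    x, y = ref.cell_centers()
    width = cfg.n_cols * cfg.cell_size
    height = cfg.n_rows * cfg.cell_size
    ridge_field = np.zeros((cfg.n_rows, cfg.n_cols))
    for _ in range(cfg.n_ridges):
        p0 = rng.uniform([0.1 * width, 0.1 * height], [0.9 * width, 0.9 * height])
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(0.4, 0.9) * max(width, height)
        p1 = p0 + length * np.array([np.cos(angle), np.sin(angle)])
        d = _point_segment_distance(x, y, p0, p1)
        bump = np.exp(-(d ** 2) / (2 * cfg.smoothing_scale ** 2))
        ridge_field = np.maximum(ridge_field, bump)
    elev = cfg.base_elevation + cfg.ridge_amplitude * ridge_field
    if cfg.noise_sd > 0:
        elev = elev + rng.normal(0.0, cfg.noise_sd, elev.shape)
    return Grid(elev, cell_size=cfg.cell_size)


def make_regions(reference: Grid, n_regions: int = 2) -> Grid:
    """Partition the grid into ``n_regions`` vertical bands labelled 0..k-1.

    Vertical banding is the simplest device reproducing the regional vs
    continental correlation contrast: within a band temperature tracks
    elevation; across bands the offsets decouple them.
    """
    if n_regions < 1:
        raise ConfigurationError("n_regions must be >= 1")
    cols = np.arange(reference.n_cols)
    band = np.minimum((cols * n_regions) // reference.n_cols, n_regions - 1)
    regions = np.broadcast_to(band, reference.shape).copy()
    out = reference.like(regions.astype(int))
    out.nodata_value = -1
    return out


def derive_climate(elev: Grid, cfg: ClimateConfig, regions: Grid) -> dict[str, Grid]:
    """Derive bioclim-style climate surfaces from elevation and regions.

    Returns grids keyed by the standard variable codes:

    * ``B10`` — mean temperature of the warmest quarter (the primary
      temperature surface, affine in elevation within a region);
    * ``B8``  — mean temperature of the wettest quarter (B10 shifted);
    * ``B4``  — temperature seasonality (its own elevation trend);
    * ``B12`` — annual precipitation (increasing with elevation);
    * ``B15`` — precipitation seasonality;
    * ``B17`` — precipitation of the driest quarter (share of B12).
    """
    cfg.validate()
    elev.require_aligned(regions, "elevation and region grids")
    rng = np.random.default_rng(cfg.seed)
    z = np.asarray(elev.values, dtype=float)
    labels = np.asarray(regions.values).astype(int)
    offsets = np.zeros(elev.shape)
    present = set(np.unique(labels).tolist())
    missing = present - set(cfg.region_offsets)
    if missing:
        raise ConfigurationError(f"regions without temperature offset: {sorted(missing)}")
    for lab, off in cfg.region_offsets.items():
        offsets[labels == lab] = off

    def noise(scale: float) -> np.ndarray:
        if cfg.noise_sd == 0:
            return np.zeros(elev.shape)
        return rng.normal(0.0, cfg.noise_sd * scale, elev.shape)

    b10 = cfg.sea_level_temp - cfg.lapse_rate * z / 1000.0 + offsets + noise(1.0)
    b8 = b10 - 4.0 + noise(1.0)
    b4 = 450.0 + 0.12 * z + 20.0 * offsets + noise(20.0)
    b12 = cfg.precip_base + cfg.precip_elev_slope * z / 1000.0 + noise(40.0)
    b15 = 45.0 - 0.006 * z + noise(2.0)
    b17 = 0.12 * b12 + noise(8.0)
    return {k: elev.like(v) for k, v in
            {"B10": b10, "B8": b8, "B4": b4, "B12": b12, "B15": b15, "B17": b17}.items()}


def derive_landcover(
    elev: Grid, temperature: Grid, seed: int, rules: LandcoverRules | None = None
) -> Grid:
    """Assign each cell one of the six broad land-cover classes."""
    rules = rules or LandcoverRules()
    elev.require_aligned(temperature, "elevation and temperature grids")
    rng = np.random.default_rng(seed)
    z = np.asarray(elev.values, dtype=float)
    t = np.asarray(temperature.values, dtype=float)
    u = rng.random(elev.shape)
    out = np.full(elev.shape, LC_OPEN, dtype=int)
    # later assignments override earlier ones: apply rules in reverse priority
    out[t >= rules.forest_min_temp] = LC_FOREST
    out[t >= rules.agri_min_temp] = LC_AGRI
    urban = (
        (u < rules.urban_fraction)
        & (z < rules.urban_max_elevation)
        & (t >= rules.urban_min_temp)
    )
    out[urban] = LC_URBAN
    out[z < rules.water_elevation] = LC_WATER
    out[t < rules.ice_temp] = LC_ICE
    grid = elev.like(out)
    grid.nodata_value = -1
    return grid


def build_suitability(
    stack: terrain.PredictorStack, response_terms: list[tuple[str, str, dict]]
) -> Grid:
    """Suitability in [0, 1] as a product of per-predictor responses.

    Shapes: ``linear`` (params lo, hi — ramp from 0 at lo to 1 at hi,
    decreasing if hi < lo), ``gaussian`` (params optimum, width) and
    ``threshold`` (params cutoff, above=True).  The product is rescaled
    so its maximum over valid cells is 1.
    """
    if not response_terms:
        raise ConfigurationError("at least one response term required")
    suit = np.ones(stack.reference.shape)
    for name, shape, params in response_terms:
        if name not in stack.grids:
            raise ConfigurationError(f"response term refers to unknown predictor {name!r}")
        v = np.asarray(stack.grids[name].values, dtype=float)
        if shape == "linear":
            lo, hi = params["lo"], params["hi"]
            r = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
        elif shape == "gaussian":
            r = np.exp(-((v - params["optimum"]) ** 2) / (2 * params["width"] ** 2))
        elif shape == "threshold":
            above = params.get("above", True)
            r = (v >= params["cutoff"]) if above else (v <= params["cutoff"])
            r = r.astype(float)
        else:
            raise ConfigurationError(f"unknown response shape {shape!r}")
        suit = suit * r
    valid = stack.mask
    suit[~valid] = np.nan
    peak = np.nanmax(suit) if valid.any() else 0.0
    if peak > 0:
        suit = suit / peak
    return stack.reference.like(suit)


def sample_virtual_occurrences(
    suitability: Grid, cfg: VirtualSpeciesConfig, regions: Grid | None = None
) -> pd.DataFrame:
    """Draw presence records cell-wise with probability ∝ suitability.

    Records get coordinates jittered uniformly within the sampled cell,
    plus uncertainty, source-type, region and verification metadata.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    vals = np.asarray(suitability.values, dtype=float)
    valid = suitability.mask & (vals > 0)
    if not valid.any() or np.nansum(vals[valid]) <= 0:
        raise SamplingError("suitability is zero everywhere; cannot sample presences")
    rows, cols = np.nonzero(valid)
    p = vals[rows, cols]
    p = p / p.sum()
    draws = rng.choice(len(rows), size=cfg.n_presences, p=p, replace=True)
    r, c = rows[draws], cols[draws]
    x, y = suitability.xy_of(r, c)
    jitter = rng.uniform(-0.45, 0.45, size=(cfg.n_presences, 2)) * suitability.cell_size
    x = x + jitter[:, 0]
    y = y + jitter[:, 1]
    if regions is not None:
        region = np.asarray(regions.values).astype(int)[r, c].astype(str)
    else:
        region = np.full(cfg.n_presences, "", dtype=object)
    records = pd.DataFrame(
        {
            "species": cfg.species,
            "lon": x,
            "lat": y,
            "uncertainty_m": rng.uniform(0.0, cfg.uncertainty_range, cfg.n_presences),
            "source_type": rng.choice(list(cfg.source_types), size=cfg.n_presences),
            "region": region,
            "verified": rng.random(cfg.n_presences) < cfg.verified_fraction,
        }
    )
    return records


def generate_range_polygons(
    template: RangeMask, overlap_fraction: float, seed: int
) -> RangeMask:
    """A comparison range mask intersecting the template in a controlled
    fraction of its area.

    The returned mask has the same cell count as the template: a seeded
    sample of ``overlap_fraction·|T|`` template cells, topped up with the
    non-template cells closest to the template centroid.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ConfigurationError("overlap_fraction must be in [0, 1]")
    if template.is_empty:
        raise GeometryError("template range mask is empty")
    rng = np.random.default_rng(seed)
    tvals = template.grid.values
    in_rows, in_cols = np.nonzero(tvals)
    n_t = len(in_rows)
    k = int(round(overlap_fraction * n_t))
    order = rng.permutation(n_t)
    keep = order[:k]
    out = np.zeros_like(tvals)
    out[in_rows[keep], in_cols[keep]] = True
    n_out = n_t - k
    if n_out > 0:
        out_rows, out_cols = np.nonzero(~tvals)
        if len(out_rows) < n_out:
            raise GeometryError("not enough cells outside the template to build the range")
        cy, cx = in_rows.mean(), in_cols.mean()
        d = np.hypot(out_rows - cy, out_cols - cx)
        nearest = np.argsort(d, kind="stable")[:n_out]
        out[out_rows[nearest], out_cols[nearest]] = True
    return RangeMask(grid=template.grid.like(out), species_id=f"synthetic_{overlap_fraction:g}")


def mask_to_polygon(mask: RangeMask):
    """Union of cell boxes of a range mask, as a shapely geometry.

    Intended for GeoJSON export of small synthetic ranges.
    """
    import shapely
    from shapely.ops import unary_union

    rows, cols = np.nonzero(mask.grid.values)
    if len(rows) == 0:
        raise GeometryError("cannot polygonize an empty mask")
    g = mask.grid
    x0, y0 = g.origin
    cs = g.cell_size
    boxes = [
        shapely.box(x0 + c * cs, y0 + (g.n_rows - r - 1) * cs,
                    x0 + (c + 1) * cs, y0 + (g.n_rows - r) * cs)
        for r, c in zip(rows, cols)
    ]
    return unary_union(boxes)


# -- assembled datasets ---------------------------------------------------

def make_broad_dataset(
    seed: int = 0,
    landscape: LandscapeConfig | None = None,
    climate: ClimateConfig | None = None,
    n_regions: int = 2,
    abruptness_radius: float = 5000.0,
) -> dict:
    """Build the full broad-scale synthetic input set.

    Returns a dict with ``elev``, ``regions``, ``landcover`` grids and a
    predictor ``stack`` holding ELEV, ABR, the six climate surfaces and
    categorical LAND.
    """
    landscape = landscape or LandscapeConfig(seed=seed)
    climate = climate or ClimateConfig(
        seed=seed + 1,
        region_offsets={i: 8.0 * i for i in range(n_regions)},
    )
    elev = generate_landscape(landscape)
    regions = make_regions(elev, n_regions)
    clim = derive_climate(elev, climate, regions)
    landcover = derive_landcover(elev, clim["B10"], seed=seed + 2)
    stack = terrain.PredictorStack(
        grids={
            "ELEV": elev,
            "ABR": terrain.abruptness(elev, radius=abruptness_radius),
            **clim,
            "LAND": landcover,
        },
        categorical={"LAND"},
        categories={"LAND": LANDCOVER_NAMES},
    )
    return {"elev": elev, "regions": regions, "landcover": landcover,
            "climate": clim, "stack": stack}


def make_fine_dataset(seed: int = 0, n_rows: int = 150, n_cols: int = 150) -> dict:
    """Build the fine-scale synthetic input set (100 m resolution).

    Predictors are ELEV, SLO, ORI and distance-to-class rasters from a
    rock/forest/urban/meadow land cover; no climate surfaces, mirroring
    the fine-scale menu where climate is collinear with elevation.
    """
    landscape = LandscapeConfig(
        n_rows=n_rows, n_cols=n_cols, cell_size=100.0, n_ridges=2,
        ridge_amplitude=1400.0, base_elevation=800.0, smoothing_scale=800.0,
        noise_sd=5.0, seed=seed,
    )
    elev = generate_landscape(landscape)
    slo = terrain.slope(elev)
    ori = terrain.aspect(elev)
    rng = np.random.default_rng(seed + 1)
    z = np.asarray(elev.values, dtype=float)
    s = np.nan_to_num(np.asarray(slo.values, dtype=float))
    u = rng.random(elev.shape)
    lc = np.full(elev.shape, FINE_MEADOW, dtype=int)
    lc[z < 1400] = FINE_FOREST
    lc[(u < 0.02) & (z < 1200)] = FINE_URBAN
    # rock outcrops on the steepest flanks and summit zone (~20% of cells)
    lc[(s > 35) | (z > 2100)] = FINE_ROCK
    landcover = elev.like(lc)
    landcover.nodata_value = -1
    stack = terrain.PredictorStack(
        grids={
            "ELEV": elev,
            "SLO": slo,
            "ORI": ori,
            "DIS-ROCK": terrain.distance_to_class(landcover, FINE_ROCK),
            "DIS-FOREST": terrain.distance_to_class(landcover, FINE_FOREST),
            "DIS-URBAN": terrain.distance_to_class(landcover, FINE_URBAN),
        }
    )
    return {"elev": elev, "landcover": landcover, "stack": stack}
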