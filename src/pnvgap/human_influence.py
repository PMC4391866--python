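"""The two-step human-influence framework: conversion plus four pressure indicators.

Step one scores outright conversion: cells converted to urban areas or
roads score 100; elsewhere the conversion score C equals the cropland
percentage. Step two scores the relative human pressure on the remaining
natural vegetation with four indicators, each on a 0-100 scale:

* VTI — vegetation transformation: mean over four observed land-cover maps
  of 25 points per physiognomy step the observed cover sits below the
  potential natural vegetation (steps beyond four still score 100; observed
  cover at or above the potential level scores 0).
* HPI — human population density: linear from 0 at 0 to 100 at 20
  persons/km^2, saturated above.
* AI — accessibility: linear from 100 at 0 h to 0 at 6 h travel time to the
  nearest high-population-density area, 0 beyond; travel time is a
  least-cost accumulation over a friction surface with roads as fast
  corridors and rivers as barriers.
* LPI — livestock grazing pressure: the feed requirement / availability
  ratio, capped at 1, times 100.

The composite is HI = C + mean(VTI, HPI, AI, LPI) * (100 - C) / 100:
pressure indicators act only on the non-converted share of a cell, so the
index estimates loss plus potential degradation of the natural vegetation
without assuming converted land has zero biodiversity value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .rasterstack_io import GridSpec, Raster, zonal_stat
from .protection_coverage import PNVMap

__all__ = [
    "DEFAULT_INTAKE_KG_PER_DAY",
    "HIConfig",
    "IndicatorStack",
    "FrictionModel",
    "LivestockModel",
    "HIResult",
    "conversion_score",
    "vegetation_transformation_index",
    "population_density_index",
    "build_friction",
    "travel_time",
    "accessibility_index",
    "livestock_pressure_index",
    "compose_hi",
    "compute_human_influence",
]

#: Daily dry-matter intake, kg/head/day. Based on a 250 kg tropical livestock
#: unit eating 2.5 % of its body weight per day; goats and sheep count as
#: 0.2 TLU.
DEFAULT_INTAKE_KG_PER_DAY = {"cattle": 6.25, "goat": 1.25, "sheep": 1.25}


@dataclass(frozen=True)
class HIConfig:
    """Tunables of the indicator framework, with their field defaults.

    Speeds in km/h, densities in persons/km^2, travel ceiling in hours.
    ``lpi_literal_one_minus`` switches the livestock index to the literal
    "1 - ratio" reading (see methods note); the default is the capped-ratio
    reading, under which more livestock means more pressure.
    """

    road_speed_kmh: float = 60.0
    offroad_speed_kmh: float = 4.0
    destination_density: float = 1000.0
    max_travel_hours: float = 6.0
    hpi_saturation_density: float = 20.0
    intake_kg_per_day: dict = field(default_factory=lambda: dict(DEFAULT_INTAKE_KG_PER_DAY))
    lpi_literal_one_minus: bool = False


@dataclass
class IndicatorStack:
    vti: Raster
    hpi: Raster
    ai: Raster
    lpi: Raster

    def __post_init__(self) -> None:
        g = self.vti.grid
        for name in ("hpi", "ai", "lpi"):
            if getattr(self, name).grid != g:
                raise ValueError("indicator rasters must be co-registered")
        for name in ("vti", "hpi", "ai", "lpi"):
            r = getattr(self, name)
            v = r.values[r.valid]
            if v.size and (v.min() < 0 or v.max() > 100):
                raise ValueError(f"{name} values outside [0, 100]")

    def mean(self) -> np.ndarray:
        return (self.vti.values + self.hpi.values + self.ai.values + self.lpi.values) / 4.0


@dataclass
class FrictionModel:
    speed_kmh: Raster
    barrier_mask: np.ndarray
    destination_mask: np.ndarray

    def __post_init__(self) -> None:
        v = self.speed_kmh.values[self.speed_kmh.valid & ~self.barrier_mask]
        if v.size and v.min() <= 0:
            raise ValueError("speeds must be positive on traversable cells")


@dataclass
class LivestockModel:
    densities: dict[str, Raster]
    intake_kg_per_day: dict[str, float]
    feed_availability: Raster


@dataclass
class HIResult:
    hi: Raster
    hi_pnv: pd.DataFrame | None = None


def conversion_score(cropland_fraction: Raster, urban_mask: Raster, road_mask: Raster) -> Raster:
    """Percent of each cell converted: 100 on urban or road cells, else cropland %."""
    cf = cropland_fraction.values
    ok = cropland_fraction.valid
    if ok.any() and (cf[ok].min() < 0 or cf[ok].max() > 1):
        raise ValueError("cropland_fraction must lie in [0, 1]")
    converted = urban_mask.values.astype(bool) | road_mask.values.astype(bool)
    score = np.where(converted, 100.0, 100.0 * cf)
    mask = cropland_fraction.mask | urban_mask.mask | road_mask.mask
    return Raster(cropland_fraction.grid, np.where(mask, 0.0, score), mask)


def vegetation_transformation_index(pnv_physiognomy: Raster, luc_maps: list[Raster]) -> Raster:
    """Mean degradation score over the observed land-cover maps.

    25 points per physiognomy step below the potential level, capped at 100
    (a five-step drop still scores 100); observed cover at or above the
    potential level scores 0.
    """
    phys = pnv_physiognomy.values.astype(np.int64)
    mask = pnv_physiognomy.mask.copy()
    total = np.zeros(phys.shape)
    for luc in luc_maps:
        lv = luc.values.astype(np.int64)
        lv_ok = lv[luc.valid]
        if lv_ok.size and (lv_ok.min() < 1 or lv_ok.max() > 6):
            raise ValueError("land-cover physiognomy levels must lie in 1..6")
        steps = np.maximum(lv - phys, 0)
        total += np.minimum(25.0 * steps, 100.0)
        mask |= luc.mask
    vti = total / len(luc_maps)
    return Raster(pnv_physiognomy.grid, np.where(mask, 0.0, vti), mask)


def population_density_index(density: Raster, saturation: float = 20.0) -> Raster:
    """Linear 0-100 score saturating at ``saturation`` persons/km^2."""
    d = density.values
    if d[density.valid].size and d[density.valid].min() < 0:
        raise ValueError("population density must be non-negative")
    score = np.minimum(d / saturation, 1.0) * 100.0
    return Raster(density.grid, np.where(density.mask, 0.0, score), density.mask.copy())


def build_friction(grid: GridSpec, road_mask: Raster, river_mask: Raster,
                   population: Raster, settlement_mask: Raster | None = None,
                   config: HIConfig = HIConfig()) -> FrictionModel:
    """Friction surface: fast on roads, slow off-road, impassable on rivers.

    A road crossing the river counts as a bridge (traversable). Destinations
    are cells above the high-density threshold, plus marked settlements.
    """
    road = road_mask.values.astype(bool)
    barrier = river_mask.values.astype(bool) & ~road
    speed = np.where(road, config.road_speed_kmh, config.offroad_speed_kmh)
    dest = population.values > config.destination_density
    if settlement_mask is not None:
        dest |= settlement_mask.values.astype(bool)
    dest &= ~barrier
    return FrictionModel(Raster(grid, speed), barrier, dest)


def travel_time(friction: FrictionModel) -> Raster:
    """Hours of least-cost travel to the nearest destination cell.

    8-connected moves; a step between adjacent cells costs the center-to-
    center distance divided by the harmonic mean of the two cells' speeds
    (half the step in each cell, time-additive and symmetric). Barrier cells
    cannot be entered; cells with no path get +inf.
    """
    grid = friction.speed_kmh.grid
    nr, nc = grid.shape
    traversable = friction.speed_kmh.valid & ~friction.barrier_mask
    dest = friction.destination_mask & traversable
    if not dest.any():
        raise ValueError("no traversable destination cells")
    node = np.arange(nr * nc).reshape(nr, nc)
    cell_km = grid.cell_size / 1000.0
    inv_v = np.where(traversable, 1.0 / friction.speed_kmh.values, np.nan)

    rows, cols, weights = [], [], []
    # offsets covering each undirected 8-neighbour pair once
    for di, dj, dist in ((0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))):
        a_i = slice(0, nr - di)
        a_j = slice(max(0, -dj), nc - max(0, dj))
        b_i = slice(di, nr)
        b_j = slice(max(0, dj), nc - max(0, -dj))
        ok = traversable[a_i, a_j] & traversable[b_i, b_j]
        w = dist * cell_km * 0.5 * (inv_v[a_i, a_j] + inv_v[b_i, b_j])
        rows.append(node[a_i, a_j][ok])
        cols.append(node[b_i, b_j][ok])
        weights.append(w[ok])
    graph = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nr * nc, nr * nc),
    ).tocsr()
    hours = dijkstra(graph, directed=False, indices=node[dest], min_only=True)
    hours = hours.reshape(nr, nc)
    hours[~traversable] = np.inf
    return Raster(grid, hours, ~friction.speed_kmh.valid)


def accessibility_index(hours: Raster, max_hours: float = 6.0) -> Raster:
    """Linear 100 at 0 h to 0 at ``max_hours``; 0 beyond (incl. unreachable)."""
    h = hours.values
    if h[hours.valid].size and np.nanmin(h[hours.valid]) < 0:
        raise ValueError("travel times must be non-negative")
    score = np.clip((max_hours - h) / max_hours, 0.0, 1.0) * 100.0
    score = np.where(np.isfinite(h), score, 0.0)
    return Raster(hours.grid, np.where(hours.mask, 0.0, score), hours.mask.copy())


def livestock_pressure_index(model: LivestockModel, literal_one_minus: bool = False) -> Raster:
    """Feed requirement / availability ratio, capped at 1, times 100.

    Requirement is the per-species density times daily dry-matter intake,
    summed over species; availability is a per-cell layer in the same units
    (kg DM / km^2 / day). ``literal_one_minus`` gives the alternative
    ``(1 - ratio)`` reading instead of the capped ratio.
    """
    avail = model.feed_availability.values
    mask = model.feed_availability.mask.copy()
    if (avail[~mask] <= 0).any():
        raise ValueError("feed availability must be positive where evaluated")
    req = np.zeros(avail.shape)
    for species, dens in model.densities.items():
        if species not in model.intake_kg_per_day:
            raise ValueError(f"no intake coefficient for species {species!r}")
        d = dens.values
        if (d[dens.valid] < 0).any():
            raise ValueError(f"negative {species} density")
        req = req + d * model.intake_kg_per_day[species]
        mask |= dens.mask
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mask, 0.0, req / avail)
    if literal_one_minus:
        score = np.clip(1.0 - ratio, 0.0, 1.0) * 100.0
    else:
        score = np.minimum(ratio, 1.0) * 100.0
    return Raster(model.feed_availability.grid, score, mask)


def compose_hi(conversion: Raster, indicators: IndicatorStack,
               pnv: PNVMap | None = None) -> HIResult:
    """HI = C + mean(indicators) * (100 - C) / 100, plus per-PNV means.

    ``hi_pnv`` is the unweighted mean of HI over each PNV's unmasked cells
    (cells are equal-area, so this is area weighting); included when a PNV
    map is supplied.
    """
    c = conversion.values
    ok = conversion.valid
    if ok.any() and (c[ok].min() < 0 or c[ok].max() > 100):
        raise ValueError("conversion score outside [0, 100]")
    hi_vals = c + indicators.mean() * (100.0 - c) / 100.0
    mask = conversion.mask | indicators.vti.mask | indicators.hpi.mask \
        | indicators.ai.mask | indicators.lpi.mask
    hi = Raster(conversion.grid, np.where(mask, 0.0, hi_vals), mask)
    hi_pnv = None
    if pnv is not None:
        hi_pnv = zonal_stat(hi, pnv.codes, "mean").rename(
            columns={"zone": "pnv_code", "value": "hi_mean"})
        sds = []
        for code in hi_pnv["pnv_code"]:
            sel = pnv.mask_for(int(code)) & hi.valid
            sds.append(float(np.std(hi.values[sel])) if sel.any() else np.nan)
        hi_pnv["hi_sd"] = sds
    return HIResult(hi, hi_pnv)


def compute_human_influence(pnv: PNVMap, luc_maps: list[Raster], cropland_fraction: Raster,
                            urban_mask: Raster, road_mask: Raster, river_mask: Raster,
                            population: Raster, livestock: dict[str, Raster],
                            feed_availability: Raster, config: HIConfig = HIConfig(),
                            settlement_mask: Raster | None = None):
    """End-to-end footprint pipeline on co-registered layers.

    Returns ``(conversion, indicators, hours, result)`` where ``result``
    carries the HI surface and the per-PNV summary (mean, sd, and the
    per-indicator per-PNV means).
    """
    grid = pnv.grid
    conv = conversion_score(cropland_fraction, urban_mask, road_mask)
    vti = vegetation_transformation_index(pnv.physiognomy, luc_maps)
    hpi = population_density_index(population, config.hpi_saturation_density)
    friction = build_friction(grid, road_mask, river_mask, population, settlement_mask, config)
    if friction.destination_mask.any():
        hours = travel_time(friction)
    else:
        # landscape without high-density areas: everything is remote
        hours = Raster(grid, np.full(grid.shape, np.inf))
    ai = accessibility_index(hours, config.max_travel_hours)
    lpi = livestock_pressure_index(
        LivestockModel(livestock, config.intake_kg_per_day, feed_availability),
        config.lpi_literal_one_minus,
    )
    indicators = IndicatorStack(vti, hpi, ai, lpi)
    result = compose_hi(conv, indicators, pnv)
    if result.hi_pnv is not None:
        for name, r in (("conversion", conv), ("vti", vti), ("hpi", hpi), ("ai", ai), ("lpi", lpi)):
            sub = zonal_stat(r, pnv.codes, "mean").rename(
                columns={"zone": "pnv_code", "value": f"{name}_mean"})
            result.hi_pnv = result.hi_pnv.merge(
                sub[["pnv_code", f"{name}_mean"]], on="pnv_code")
    return conv, indicators, hours, result
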