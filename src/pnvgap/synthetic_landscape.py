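"""Synthetic landscape generator with recorded ground truth.

Generates complete, internally consistent input stacks for the gap- and
threat-analysis pipeline: smooth correlated environmental fields, clumped
vegetation classes with an ordinal physiognomy, protected areas placed with
a controllable environmental bias, population kernels with a connecting road
network, a river acting as a travel barrier, cropland correlated with
population, land-cover degradation increasing with human pressure, and
smooth positive livestock densities. Every stochastic quantity that the
pipeline later estimates is recorded in a ``truth`` dictionary at generation
time, computed directly from the emitted layers (or exactly, where a closed
form exists), so downstream stages can be tested for parameter recovery
without external data.

Generation is a pure function of the configuration (which includes the
seed): the same config yields bit-identical landscapes.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.sparse.csgraph import minimum_spanning_tree
from shapely.geometry import box

from .rasterstack_io import (
    GridSpec,
    LayerStack,
    Raster,
    raster_checksum,
    write_raster,
)
from .protection_coverage import PNVMap, ProtectedArea, ProtectedAreaSet

__all__ = [
    "LandscapeConfig",
    "SyntheticLandscape",
    "generate",
    "generate_environment",
    "derive_pnv",
    "place_protected_areas",
    "generate_human_layers",
    "generate_luc_maps",
    "write_landscape",
    "load_landscape",
]

#: category label attached to each physiognomy level of a synthetic PNV
_PHYS_CATEGORY = {1: "forest", 2: "woodland", 3: "bushland", 4: "grassland", 5: "highland", 6: "arid"}

#: per-species multiplier on the configured mean livestock density
_SPECIES_WEIGHT = {"cattle": 1.0, "goat": 0.7, "sheep": 0.5}


@dataclass(frozen=True)
class LandscapeConfig:
    """All knobs of the generator; defaults define the standard study conditions.

    ``smoothness`` is the spatial correlation length of the environmental
    fields, in cells (1 = white noise). ``pa_env_bias`` in [-1, 1] tilts
    protected-area placement toward the high (+) or low (-) tail of the
    first environmental variable; 0 places PAs independently of environment.
    ``pop_peak`` is the population density at a town center (persons/km^2);
    town kernels decay by a Gaussian profile. Intensities are in [0, 1].
    """

    seed: int = 0
    grid: GridSpec = field(default_factory=lambda: GridSpec(100, 100, cell_size=900.0))
    n_pnv: int = 8
    env_vars: int = 6
    smoothness: float = 6.0
    n_pa: int = 60
    pa_mean_size: int = 25
    pa_env_bias: float = 0.0
    n_towns: int = 8
    pop_peak: float = 5000.0
    cropland_intensity: float = 0.3
    degradation_strength: float = 0.3
    livestock_mean_density: float = 50.0
    feed_availability_mean: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("n_pnv", "env_vars", "n_towns"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_pa < 0 or self.pa_mean_size < 1:
            raise ValueError("n_pa must be >= 0 and pa_mean_size >= 1")
        if not -1.0 <= self.pa_env_bias <= 1.0:
            raise ValueError("pa_env_bias must lie in [-1, 1]")
        for name in ("cropland_intensity", "degradation_strength"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.smoothness < 1:
            raise ValueError("smoothness must be >= 1 cell")


@dataclass
class SyntheticLandscape:
    """A full co-registered input stack plus the ground-truth record."""

    config: LandscapeConfig
    env: LayerStack
    pnv: PNVMap
    pas: ProtectedAreaSet
    population: Raster
    urban_mask: Raster
    road_mask: Raster
    river_mask: Raster
    cropland_fraction: Raster
    luc_maps: list[Raster]
    livestock: dict[str, Raster]
    feed_availability: Raster
    truth: dict

    @property
    def grid(self) -> GridSpec:
        return self.env.grid


def _smooth_field(rng: np.random.Generator, grid: GridSpec, smoothness: float) -> np.ndarray:
    """Kernel-convolved white noise, standardized to mean 0 / variance 1."""
    noise = rng.standard_normal(grid.shape)
    sigma = (smoothness - 1.0) / 2.0
    f = gaussian_filter(noise, sigma=sigma, mode="reflect") if sigma > 0 else noise
    return (f - f.mean()) / f.std()


def generate_environment(config: LandscapeConfig, rng: np.random.Generator | None = None) -> LayerStack:
    """``env_vars`` smooth correlated fields standing in for climatic predictors."""
    rng = rng or np.random.default_rng(config.seed)
    layers = {
        f"env_{k + 1:02d}": Raster(config.grid, _smooth_field(rng, config.grid, config.smoothness))
        for k in range(config.env_vars)
    }
    return LayerStack(layers)


def derive_pnv(env: LayerStack, n_pnv: int, rng: np.random.Generator | None = None) -> PNVMap:
    """Cluster the first two environmental fields into ``n_pnv`` vegetation classes.

    Classes are quantile strata of env_01, each split into quantile bins of
    env_02, so every class is non-empty and tends to be spatially contiguous
    (the fields are smooth). Each class receives an ordinal physiognomy level
    1..6 by the rank of its mean env_01 (wet end = forest, dry end =
    semi-desert) and a category label.
    """
    grid = env.grid
    names = env.names
    v1 = env[names[0]].values.ravel()
    v2 = env[names[1]].values.ravel() if len(names) > 1 else v1
    n_cells = v1.size
    if n_pnv > n_cells:
        raise ValueError(f"cannot form {n_pnv} classes on a {n_cells}-cell grid")
    k1 = max(1, int(round(np.sqrt(n_pnv))))
    per_stratum = [n_pnv // k1 + (1 if s < n_pnv % k1 else 0) for s in range(k1)]
    q1 = np.quantile(v1, np.linspace(0, 1, k1 + 1)[1:-1])
    stratum = np.searchsorted(q1, v1, side="right")
    codes = np.zeros(n_cells, dtype=np.int64)
    next_code = 1
    for s in range(k1):
        sel = stratum == s
        k2 = per_stratum[s]
        sub = v2[sel]
        q2 = np.quantile(sub, np.linspace(0, 1, k2 + 1)[1:-1])
        codes[sel] = next_code + np.searchsorted(q2, sub, side="right")
        next_code += k2
    codes_2d = codes.reshape(grid.shape)
    # physiognomy by rank of class-mean env_01: wettest class -> forest (1)
    class_codes = np.arange(1, n_pnv + 1)
    means = np.array([v1[codes == c].mean() for c in class_codes])
    order = np.argsort(-means)  # descending env_01
    phys_of_code = np.zeros(n_pnv + 1, dtype=np.int64)
    labels: dict[int, tuple[str, str]] = {}
    for rank, idx in enumerate(order):
        code = int(class_codes[idx])
        level = min(6, 1 + (rank * 6) // n_pnv)
        phys_of_code[code] = level
        cat = _PHYS_CATEGORY[level]
        labels[code] = (f"synthetic {cat} PNV {code}", cat)
    phys_2d = phys_of_code[codes_2d]
    return PNVMap(Raster(grid, codes_2d), Raster(grid, phys_2d), labels)


def place_protected_areas(env: LayerStack, pnv: PNVMap, config: LandscapeConfig,
                          rng: np.random.Generator | None = None) -> ProtectedAreaSet:
    """Axis-aligned rectangular PAs with environmentally biased acceptance.

    A candidate rectangle with mean env_01 at percentile ``u`` of the
    candidate distribution is accepted with probability ``u**(3b)`` for bias
    ``b >= 0`` (and ``(1-u)**(3|b|)`` for negative bias): bias 0 accepts
    every candidate (placement independent of environment); |bias| 1
    strongly prefers one environmental tail. The percentile reference is
    built from a pre-pass of random candidate rectangles, so the tilt acts
    on the actual sampling distribution of rectangle means. IUCN categories
    are drawn uniformly from {Ib, II, IV, VI, UNC}. Rectangles snap to cell
    boundaries so area bookkeeping under cell-center rasterization is exact.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    grid = env.grid
    if config.n_pa == 0:
        return ProtectedAreaSet()
    if config.n_pa * config.pa_mean_size > 0.8 * grid.n_rows * grid.n_cols:
        raise ValueError("grid too small for the requested number and size of protected areas")
    env1 = env[env.names[0]].values
    x0, y0 = grid.origin
    cs = grid.cell_size
    cats = ["Ib", "II", "IV", "VI", "UNC"]

    def _candidate():
        area = max(4.0, rng.normal(config.pa_mean_size, config.pa_mean_size / 3.0))
        aspect = rng.uniform(0.5, 2.0)
        h = int(np.clip(round(np.sqrt(area * aspect)), 1, grid.n_rows))
        w = int(np.clip(round(np.sqrt(area / aspect)), 1, grid.n_cols))
        r0 = int(rng.integers(0, grid.n_rows - h + 1))
        c0 = int(rng.integers(0, grid.n_cols - w + 1))
        return r0, c0, h, w, float(env1[r0:r0 + h, c0:c0 + w].mean())

    # sampling distribution of candidate rectangle means, for the percentile tilt
    ref_z = np.sort([_candidate()[4] for _ in range(500)])
    b = config.pa_env_bias
    pas = []
    attempts = 0
    max_attempts = 500 * config.n_pa
    while len(pas) < config.n_pa:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("protected-area placement did not converge; grid likely too small")
        r0, c0, h, w, z = _candidate()
        u = np.searchsorted(ref_z, z, side="right") / ref_z.size
        p_accept = u ** (3.0 * b) if b >= 0 else (1.0 - u) ** (3.0 * -b)
        if rng.random() > p_accept:
            continue
        geom = box(x0 + c0 * cs, y0 - (r0 + h) * cs, x0 + (c0 + w) * cs, y0 - r0 * cs)
        cat = cats[rng.integers(0, len(cats))]
        pas.append(ProtectedArea(geom, cat, name=f"synthetic PA {len(pas) + 1}"))
    return ProtectedAreaSet(pas)


def generate_human_layers(env: LayerStack, pnv: PNVMap, config: LandscapeConfig,
                          rng: np.random.Generator | None = None):
    """Population kernels, urban/road/river masks, cropland and livestock layers.

    Population is a sum of Gaussian town kernels peaking at ``pop_peak`` over
    a background of 1 person/km^2; cells above 1000 persons/km^2 form the
    urban mask. Roads connect the towns along a minimum spanning tree;
    a single river random-walks from the north to the south edge and acts
    as a movement barrier except where a road crosses it (a bridge).
    Cropland fraction increases with both population and a suitability field
    (env_02), scaled by ``cropland_intensity``; livestock densities are
    smooth, positive, and average to the configured per-species mean.
    """
    from skimage.draw import line as _draw_line

    rng = rng or np.random.default_rng(config.seed + 2)
    grid = config.grid
    nr, nc = grid.shape

    n_towns = config.n_towns if config.pop_peak > 0 else 0
    towns = np.column_stack([
        rng.integers(0, nr, size=n_towns),
        rng.integers(0, nc, size=n_towns),
    ])
    ii, jj = np.mgrid[0:nr, 0:nc]
    # rural background of 1 person/km^2 at the default peak, scaling with it
    pop = np.full((nr, nc), config.pop_peak * 2e-4)
    kernel_radius = max(2.0, min(nr, nc) / 20.0)
    for (ti, tj) in towns:
        d2 = (ii - ti) ** 2 + (jj - tj) ** 2
        pop += config.pop_peak * np.exp(-d2 / (2.0 * kernel_radius**2))
    population = Raster(grid, pop)
    urban = Raster(grid, pop > 1000.0)

    road = np.zeros((nr, nc), dtype=bool)
    if n_towns > 1:
        d = np.sqrt(((towns[:, None, :] - towns[None, :, :]) ** 2).sum(-1))
        mst = minimum_spanning_tree(d).tocoo()
        for a, b in zip(mst.row, mst.col):
            rr, cc = _draw_line(int(towns[a, 0]), int(towns[a, 1]), int(towns[b, 0]), int(towns[b, 1]))
            road[rr, cc] = True

    river = np.zeros((nr, nc), dtype=bool)
    col = int(rng.integers(nc // 4, 3 * nc // 4))
    for i in range(nr):
        river[i, col] = True
        col = int(np.clip(col + rng.integers(-1, 2), 0, nc - 1))
        river[i, col] = True

    suitability = _rank01(env[env.names[1 % len(env.names)]].values)
    pop_sat = pop / (pop + 20.0)
    cropland = config.cropland_intensity * (0.5 * pop_sat + 0.5 * suitability)
    cropland = Raster(grid, np.clip(cropland, 0.0, 1.0))

    livestock = {}
    for species, wgt in _SPECIES_WEIGHT.items():
        g = _smooth_field(rng, grid, config.smoothness)
        dens = np.exp(0.5 * g)
        dens *= config.livestock_mean_density * wgt / dens.mean()
        livestock[species] = Raster(grid, dens)
    feed = np.exp(0.3 * _smooth_field(rng, grid, config.smoothness))
    feed *= config.feed_availability_mean / feed.mean()
    feed_availability = Raster(grid, feed)

    return population, urban, Raster(grid, road), Raster(grid, river), cropland, livestock, feed_availability


def _rank01(values: np.ndarray) -> np.ndarray:
    """Rank-transform a field to [0, 1]."""
    flat = values.ravel()
    ranks = np.empty_like(flat)
    ranks[np.argsort(flat, kind="stable")] = np.arange(flat.size)
    return (ranks / max(1, flat.size - 1)).reshape(values.shape)


def generate_luc_maps(physiognomy: Raster, pressure01: np.ndarray, config: LandscapeConfig,
                      rng: np.random.Generator | None = None) -> tuple[list[Raster], np.ndarray]:
    """Four observed land-cover maps as degraded copies of the PNV physiognomy.

    Per cell and map, the physiognomy is stepped down (toward semi-desert) by
    ``Binomial(4, q)`` levels with ``q = degradation_strength * pressure``,
    clipped at level 6. The four maps are independent draws. Returns the maps
    and the exact per-cell expected realized step-down
    ``E[min(B, 6 - level)]`` (identical for each map), from the binomial pmf.
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    phys = physiognomy.values.astype(np.int64)
    if phys.min() < 1 or phys.max() > 6:
        raise ValueError("physiognomy levels must lie in 1..6")
    q = np.clip(config.degradation_strength * pressure01, 0.0, 1.0)
    maps = []
    for _ in range(4):
        steps = rng.binomial(4, q)
        maps.append(Raster(physiognomy.grid, np.minimum(phys + steps, 6), physiognomy.mask.copy()))
    # exact expectation of the clipped step-down
    headroom = 6 - phys
    k = np.arange(5)
    from scipy.stats import binom

    pmf = binom.pmf(k[:, None, None], 4, q[None, :, :])  # (5, nr, nc)
    expected = (pmf * np.minimum(k[:, None, None], headroom[None, :, :])).sum(axis=0)
    return maps, expected


def generate(config: LandscapeConfig) -> SyntheticLandscape:
    """Build the full landscape and its ground-truth record."""
    env = generate_environment(config)
    pnv = derive_pnv(env, config.n_pnv)
    pas = place_protected_areas(env, pnv, config)
    (population, urban, road, river, cropland, livestock, feed) = generate_human_layers(env, pnv, config)
    pop_sat = population.values / (population.values + 20.0)
    luc_maps, expected_step = generate_luc_maps(pnv.physiognomy, pop_sat, config)

    truth = _build_truth(config, env, pnv, pas, population, urban, road, cropland,
                         livestock, feed, expected_step)
    return SyntheticLandscape(
        config=config, env=env, pnv=pnv, pas=pas, population=population,
        urban_mask=urban, road_mask=road, river_mask=river,
        cropland_fraction=cropland, luc_maps=luc_maps, livestock=livestock,
        feed_availability=feed, truth=truth,
    )


def _build_truth(config, env, pnv, pas, population, urban, road, cropland,
                 livestock, feed, expected_step) -> dict:
    """Planted per-PNV quantities, recomputed directly from the layers.

    The indicator formulas here are deliberately plain numpy restatements of
    the scoring rules, independent of the pipeline modules, so recovery
    tests compare two separate code paths.
    """
    from .human_influence import DEFAULT_INTAKE_KG_PER_DAY  # coefficients only

    env1 = env[env.names[0]].values
    from .rasterstack_io import rasterize_polygons

    grid = env.grid
    if len(pas):
        pa_r = rasterize_polygons([(p.geometry, 1) for p in pas], grid, combine="max")
        pa_cells = pa_r.valid
    else:
        pa_cells = np.zeros(grid.shape, dtype=bool)
    realized_bias = float(env1[pa_cells].mean() - env1.mean()) if pa_cells.any() else 0.0

    conv = np.where(urban.values.astype(bool) | road.values.astype(bool),
                    100.0, 100.0 * cropland.values)
    hpi = np.minimum(population.values / 20.0, 1.0) * 100.0
    req = sum(livestock[s].values * DEFAULT_INTAKE_KG_PER_DAY[s] for s in livestock)
    lpi = np.minimum(req / feed.values, 1.0) * 100.0
    evti = 25.0 * expected_step
    # per-map VTI variance for the standard-error bound used in recovery tests
    var_step = _clipped_step_variance(pnv.physiognomy.values.astype(int), config, population.values)

    per_pnv = {}
    for code in pnv.code_set:
        sel = pnv.mask_for(code)
        n = int(sel.sum())
        per_pnv[str(code)] = {
            "n_cells": n,
            "converted_mean_pct": float(conv[sel].mean()),
            "hpi_mean": float(hpi[sel].mean()),
            "lpi_mean": float(lpi[sel].mean()),
            "vti_expected_mean": float(evti[sel].mean()),
            "vti_mean_se": float(25.0 / (2.0 * n) * np.sqrt(var_step[sel].sum())) if n else 0.0,
            "pa_fraction": float(pa_cells[sel].mean()),
        }
    return {
        "pa_env_bias": config.pa_env_bias,
        "realized_pa_env_bias": realized_bias,
        "per_pnv": per_pnv,
    }


def _clipped_step_variance(phys: np.ndarray, config: LandscapeConfig,
                           population: np.ndarray) -> np.ndarray:
    """Per-cell variance of the clipped step-down min(Binomial(4,q), 6-level)."""
    from scipy.stats import binom

    pop_sat = population / (population + 20.0)
    q = np.clip(config.degradation_strength * pop_sat, 0.0, 1.0)
    headroom = 6 - phys
    k = np.arange(5)
    pmf = binom.pmf(k[:, None, None], 4, q[None, :, :])
    clipped = np.minimum(k[:, None, None], headroom[None, :, :])
    m1 = (pmf * clipped).sum(axis=0)
    m2 = (pmf * clipped**2).sum(axis=0)
    return m2 - m1**2


def write_landscape(landscape: SyntheticLandscape, outdir: str | os.PathLike) -> None:
    """Write the stack as ASCII grids + GeoJSON, with truth.json and checksums.txt."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    rasters: dict[str, Raster] = {}
    for name in landscape.env.names:
        rasters[name] = landscape.env[name]
    rasters["pnv"] = landscape.pnv.codes
    rasters["physiognomy"] = landscape.pnv.physiognomy
    rasters["population"] = landscape.population
    rasters["urban"] = Raster(landscape.grid, landscape.urban_mask.values.astype(np.int64))
    rasters["road"] = Raster(landscape.grid, landscape.road_mask.values.astype(np.int64))
    rasters["river"] = Raster(landscape.grid, landscape.river_mask.values.astype(np.int64))
    rasters["cropland_fraction"] = landscape.cropland_fraction
    for k, luc in enumerate(landscape.luc_maps, start=1):
        rasters[f"luc_{k}"] = luc
    for species, r in landscape.livestock.items():
        rasters[f"livestock_{species}"] = r
    rasters["feed_availability"] = landscape.feed_availability

    checks = []
    for name, r in rasters.items():
        write_raster(r, os.path.join(outdir, f"{name}.asc"))
        checks.append(f"{name}.asc {raster_checksum(r)}")
    landscape.pas.to_geojson(os.path.join(outdir, "pas.geojson"))
    meta = dict(landscape.truth)
    cfg = asdict(landscape.config)  # nested GridSpec becomes a plain dict
    cfg["grid"]["origin"] = list(cfg["grid"]["origin"])
    meta["config"] = cfg
    meta["pnv_labels"] = {str(k): list(v) for k, v in landscape.pnv.labels.items()}
    with open(os.path.join(outdir, "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)
    with open(os.path.join(outdir, "checksums.txt"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(checks) + "\n")


def load_landscape(indir: str | os.PathLike) -> SyntheticLandscape:
    """Read back a landscape directory written by :func:`write_landscape`."""
    from .rasterstack_io import read_raster

    indir = os.fspath(indir)
    with open(os.path.join(indir, "truth.json"), "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    cfg_d = dict(meta.pop("config"))
    g = cfg_d.pop("grid")
    config = LandscapeConfig(
        grid=GridSpec(int(g["n_rows"]), int(g["n_cols"]), g["cell_size"],
                      tuple(g["origin"]), g["crs_id"]),
        **cfg_d,
    )
    labels = {int(k): tuple(v) for k, v in meta.pop("pnv_labels").items()}

    def _r(name: str) -> Raster:
        return read_raster(os.path.join(indir, f"{name}.asc"))

    env = LayerStack({f"env_{k + 1:02d}": _r(f"env_{k + 1:02d}") for k in range(config.env_vars)})
    pnv_codes = _r("pnv")
    pnv = PNVMap(
        Raster(pnv_codes.grid, pnv_codes.values.astype(np.int64), pnv_codes.mask),
        _r("physiognomy"), labels,
    )
    return SyntheticLandscape(
        config=config,
        env=env,
        pnv=pnv,
        pas=ProtectedAreaSet.from_geojson(os.path.join(indir, "pas.geojson")),
        population=_r("population"),
        urban_mask=_r("urban"),
        road_mask=_r("road"),
        river_mask=_r("river"),
        cropland_fraction=_r("cropland_fraction"),
        luc_maps=[_r(f"luc_{k}") for k in range(1, 5)],
        livestock={s: _r(f"livestock_{s}") for s in _SPECIES_WEIGHT},
        feed_availability=_r("feed_availability"),
        truth=meta,
    )
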