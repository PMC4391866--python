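"""Protected-area classification, overlap resolution and geographic coverage.

Protected areas (PAs) carry an IUCN management category. The five categories
present in the study system, plus unclassified reserves, are reduced to two
protection groups: PA1 (categories Ib, II, III, IV — explicitly designated
for biodiversity or landscape protection) and PA2 (category VI plus
unclassified reserves — protection combined with sustainable use). Where PAs
overlap, the highest-ranking IUCN category wins (Ib > II > III > IV > VI >
UNC, following the IUCN category numbering). The geographic coverage index
(GC) of a vegetation type is the percentage of its cells lying inside PAs.

None of this implies any assumption about management effectiveness; the
grouping reflects stated management objectives only.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .rasterstack_io import (
    GridAlignmentError,
    GridSpec,
    Raster,
    rasterize_polygons,
    zonal_stat,
)

__all__ = [
    "IUCN_RANK",
    "PA1",
    "PA2",
    "UNPROTECTED",
    "PNVMap",
    "ProtectedArea",
    "ProtectedAreaSet",
    "classify_protection",
    "resolve_overlaps",
    "geographic_coverage",
    "coverage_table",
    "coverage_by_country",
]

#: Severity ranking used for overlap resolution: stricter category = lower rank.
IUCN_RANK = {"Ib": 1, "II": 2, "III": 3, "IV": 4, "VI": 5, "UNC": 6}

UNPROTECTED = 0
PA1 = 1
PA2 = 2

#: ordinal physiognomy levels, from closed forest to semi-desert
PHYSIOGNOMY_LEVELS = {
    1: "forest",
    2: "open forest / woodland",
    3: "bushland, thicket and wooded grassland",
    4: "grassland and herbaceous",
    5: "stunted bushland",
    6: "semi-desert",
}

PNV_CATEGORIES = ("forest", "woodland", "bushland", "grassland", "highland", "arid")


@dataclass
class PNVMap:
    """Categorical potential-natural-vegetation raster with physiognomy levels.

    ``codes`` holds integer PNV codes (>= 1); ``physiognomy`` the ordinal
    structure level 1 (forest) .. 6 (semi-desert) of each cell's PNV;
    ``labels`` maps each code to a ``(label, category)`` pair.
    """

    codes: Raster
    physiognomy: Raster
    labels: dict[int, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.codes.grid != self.physiognomy.grid:
            raise GridAlignmentError("PNV codes and physiognomy must be co-registered")
        phys = self.physiognomy.values[self.physiognomy.valid]
        if phys.size and (phys.min() < 1 or phys.max() > 6):
            raise ValueError("physiognomy levels must lie in 1..6")

    @property
    def grid(self) -> GridSpec:
        return self.codes.grid

    @property
    def code_set(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.codes.values[self.codes.valid]))

    def mask_for(self, code: int) -> np.ndarray:
        return self.codes.valid & (self.codes.values == code)


@dataclass
class ProtectedArea:
    geometry: BaseGeometry
    iucn_cat: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.iucn_cat not in IUCN_RANK:
            raise ValueError(
                f"unknown IUCN category {self.iucn_cat!r} for PA {self.name!r}; "
                f"expected one of {sorted(IUCN_RANK)}"
            )
        if not self.geometry.is_valid:
            raise ValueError(f"invalid geometry for PA {self.name!r}")

    @property
    def rank(self) -> int:
        return IUCN_RANK[self.iucn_cat]

    @property
    def protection_group(self) -> int:
        return classify_protection(self.iucn_cat)


class ProtectedAreaSet(Sequence[ProtectedArea]):
    """An ordered collection of protected areas, readable from GeoJSON.

    The GeoJSON reader keeps only polygonal, nationally designated features:
    point features and features whose ``status`` property is ``"Proposed"``
    are dropped at read time.
    """

    def __init__(self, pas: Iterable[ProtectedArea] = ()):
        self._pas = list(pas)

    def __getitem__(self, idx):  # type: ignore[override]
        return self._pas[idx]

    def __len__(self) -> int:
        return len(self._pas)

    def __iter__(self) -> Iterator[ProtectedArea]:
        return iter(self._pas)

    @classmethod
    def from_geojson(cls, path: str | os.PathLike) -> "ProtectedAreaSet":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        pas = []
        for feat in doc.get("features", []):
            props = feat.get("properties") or {}
            if str(props.get("status", "")).lower() == "proposed":
                continue
            geom = shape(feat["geometry"])
            if geom.geom_type not in ("Polygon", "MultiPolygon"):
                continue
            pas.append(ProtectedArea(geom, props["iucn_cat"], props.get("name", "")))
        return cls(pas)

    def to_geojson(self, path: str | os.PathLike) -> None:
        feats = [
            {
                "type": "Feature",
                "geometry": mapping(pa.geometry),
                "properties": {"iucn_cat": pa.iucn_cat, "name": pa.name},
            }
            for pa in self._pas
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def classify_protection(iucn_cat: str) -> int:
    """Reduce an IUCN category to a protection group (PA1=1 or PA2=2).

    Ib, II, III and IV form PA1; VI and unclassified (UNC) reserves form
    PA2. An unknown category is an error — never silently defaulted.
    """
    if iucn_cat in ("Ib", "II", "III", "IV"):
        return PA1
    if iucn_cat in ("VI", "UNC"):
        return PA2
    raise ValueError(f"unknown IUCN category {iucn_cat!r}")


def resolve_overlaps(pas: ProtectedAreaSet, grid: GridSpec) -> Raster:
    """Rasterize PAs to a {0, PA1, PA2} protection raster.

    Cell membership is by cell-center containment. Where several PAs cover a
    cell, the highest IUCN classification ranking wins (Ib > II > III > IV >
    VI > UNC) before the PA1/PA2 reduction. The output raster is unmasked:
    uncovered cells carry code 0 (unprotected).
    """
    if len(pas) == 0:
        return Raster(grid, np.zeros(grid.shape, dtype=np.int64))
    ranked = rasterize_polygons([(pa.geometry, pa.rank) for pa in pas], grid, combine="min")
    rank_to_group = np.zeros(max(IUCN_RANK.values()) + 1, dtype=np.int64)
    for cat, rank in IUCN_RANK.items():
        rank_to_group[rank] = classify_protection(cat)
    codes = np.zeros(grid.shape, dtype=np.int64)
    cov = ranked.valid
    codes[cov] = rank_to_group[ranked.values[cov].astype(np.int64)]
    return Raster(grid, codes)


def geographic_coverage(pnv: PNVMap, protection: Raster, subset: str = "all") -> pd.DataFrame:
    """Percent of each PNV's cells lying in protected areas (the GC index).

    ``subset="all"`` counts PA1 and PA2 cells; ``subset="pa1_only"`` counts
    PA1 cells only. PNVs with no unmasked cells get NaN, not 0 — an empty
    vegetation type has undefined, not zero, coverage.
    """
    if subset not in ("all", "pa1_only"):
        raise ValueError(f"unknown subset {subset!r}")
    pred = (lambda v: v >= PA1) if subset == "all" else (lambda v: v == PA1)
    df = zonal_stat(protection, pnv.codes, "percent_where", predicate=pred)
    return df.rename(columns={"zone": "pnv_code", "value": "gc_pct", "n_cells": "area_cells"})


def coverage_table(pnv: PNVMap, protection: Raster) -> pd.DataFrame:
    """Joined per-PNV coverage record: gc_all_pct, gc_pa1_pct, area, labels."""
    gc_all = geographic_coverage(pnv, protection, "all")
    gc_pa1 = geographic_coverage(pnv, protection, "pa1_only")
    df = gc_all.rename(columns={"gc_pct": "gc_all_pct"}).merge(
        gc_pa1[["pnv_code", "gc_pct"]].rename(columns={"gc_pct": "gc_pa1_pct"}),
        on="pnv_code",
    )
    df["pnv_label"] = [pnv.labels.get(c, ("", ""))[0] for c in df["pnv_code"]]
    df["category"] = [pnv.labels.get(c, ("", ""))[1] for c in df["pnv_code"]]
    return df[["pnv_code", "pnv_label", "category", "area_cells", "gc_all_pct", "gc_pa1_pct"]]


def coverage_by_country(pnv: PNVMap, protection: Raster, countries: Raster) -> pd.DataFrame:
    """GC within each country x PNV intersection, plus per-country totals.

    Per-country totals (GC over all the country's cells regardless of PNV)
    appear as rows with ``pnv_code`` -1.
    """
    if countries.grid != pnv.grid or countries.grid != protection.grid:
        raise GridAlignmentError("countries raster must be co-registered with PNV and protection")
    rows = []
    ccodes = np.unique(countries.values[countries.valid]).astype(np.int64)
    for c in ccodes:
        in_c = countries.valid & (countries.values == c)
        sub_codes = Raster(pnv.grid, pnv.codes.values, pnv.codes.mask | ~in_c)
        sub_pnv = PNVMap(sub_codes, pnv.physiognomy, pnv.labels)
        tab = coverage_table(sub_pnv, protection)
        tab.insert(0, "country", int(c))
        rows.append(tab)
        prot_c = protection.values[in_c]
        n = prot_c.size
        rows.append(
            pd.DataFrame(
                [
                    {
                        "country": int(c),
                        "pnv_code": -1,
                        "pnv_label": "(all)",
                        "category": "",
                        "area_cells": n,
                        "gc_all_pct": 100.0 * np.count_nonzero(prot_c >= PA1) / n if n else np.nan,
                        "gc_pa1_pct": 100.0 * np.count_nonzero(prot_c == PA1) / n if n else np.nan,
                    }
                ]
            )
        )
    return pd.concat(rows, ignore_index=True)
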