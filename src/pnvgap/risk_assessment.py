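"""Conservation-risk classification of vegetation types.

A vegetation type (PNV) with high human influence and little protection is
at risk. The conservation risk index is the ratio

    CRI = HI_pnv / GC

of the PNV's mean human influence to its percent area protected; an
unprotected PNV (GC = 0) with any human influence has infinite CRI. A PNV
is then classified by the first matching rule, in severity order:

* default scheme  — CR: HI > 50 and CRI > 10; EN: HI > 40 and CRI > 4;
  VU: HI > 20 and CRI > 2; otherwise NV.
* "hoekstra" scheme — the same HI bounds with CRI bounds 25, 10 and 2
  (the thresholds of the global crisis-ecoregion framework).

All inequalities are strict. The rules are nested: whatever satisfies the
CR rule also satisfies EN and VU, so evaluation order is severity order.
Classification is run twice per PNV, once with GC from all protected areas
and once counting only the strictly protected PA1 group.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import inf, isnan

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RiskThresholds",
    "PAPER_SCHEME",
    "HOEKSTRA_SCHEME",
    "SCHEMES",
    "CLASS_SEVERITY",
    "conservation_risk_index",
    "classify_risk",
    "classify_eb_band",
    "build_risk_table",
    "crisis_pnvs",
    "summary_statistics",
]

#: higher = more severe
CLASS_SEVERITY = {"NV": 0, "VU": 1, "EN": 2, "CR": 3}


@dataclass(frozen=True)
class RiskThresholds:
    """Ordered (label, HI bound, CRI bound) rules; strict '>' comparisons."""

    name: str
    rules: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("threshold scheme needs at least one rule")
        last = inf
        for label, hi_min, cri_min in self.rules:
            if label not in CLASS_SEVERITY:
                raise ValueError(f"unknown class label {label!r}")
            if hi_min <= 0 or cri_min <= 0:
                raise ValueError("thresholds must be positive")
            if CLASS_SEVERITY[label] >= last:
                raise ValueError("rules must be ordered from most to least severe")
            last = CLASS_SEVERITY[label]


PAPER_SCHEME = RiskThresholds("default", (("CR", 50, 10), ("EN", 40, 4), ("VU", 20, 2)))
HOEKSTRA_SCHEME = RiskThresholds("hoekstra", (("CR", 50, 25), ("EN", 40, 10), ("VU", 20, 2)))
SCHEMES = {"default": PAPER_SCHEME, "paper": PAPER_SCHEME, "hoekstra": HOEKSTRA_SCHEME}


def conservation_risk_index(hi_pnv: float, gc: float) -> float:
    """HI_pnv / GC, with the limit conventions at GC = 0.

    A fully unprotected PNV under any human influence gets +inf, so it
    classifies by its HI bound alone rather than dropping out; zero
    influence gives 0 regardless of protection.
    """
    if not 0 <= hi_pnv <= 100:
        raise ValueError(f"hi_pnv out of range: {hi_pnv}")
    if not 0 <= gc <= 100:
        raise ValueError(f"gc out of range: {gc}")
    if gc == 0:
        return inf if hi_pnv > 0 else 0.0
    return hi_pnv / gc


def classify_risk(hi_pnv: float, cri: float, thresholds: RiskThresholds = PAPER_SCHEME) -> str:
    """First matching rule in severity order; NV when none matches."""
    if isnan(hi_pnv) or isnan(cri):
        return "NV"
    for label, hi_min, cri_min in thresholds.rules:
        if hi_pnv > hi_min and cri > cri_min:
            return label
    return "NV"


def classify_eb_band(eb: float) -> str:
    """Environmental-bias band: HB (> 1), MB (0.5 <= EB < 1), LB (< 0.5)."""
    if isnan(eb):
        return "LB"
    if eb > 1:
        return "HB"
    if eb >= 0.5:
        return "MB"
    return "LB"


def build_risk_table(coverage: pd.DataFrame, hi_pnv: pd.DataFrame,
                     eb: pd.DataFrame | None = None,
                     schemes: dict[str, RiskThresholds] | None = None) -> pd.DataFrame:
    """Join coverage, human influence and bias into per-PNV risk records.

    ``coverage`` needs columns pnv_code, gc_all_pct, gc_pa1_pct (and
    optionally area_cells); ``hi_pnv`` needs pnv_code, hi_mean; ``eb``
    (optional) pnv_code, eb. All tables must cover the same PNV codes. For
    each scheme the table gains class columns computed with GC from all PAs
    (``class_all``) and from PA1 only (``class_pa1``).
    """
    schemes = schemes or {"default": PAPER_SCHEME}
    cov_codes = set(coverage["pnv_code"])
    hi_codes = set(hi_pnv["pnv_code"])
    if cov_codes != hi_codes:
        raise ValueError(f"PNV code mismatch between coverage and HI tables: "
                         f"{sorted(cov_codes ^ hi_codes)}")
    df = coverage.merge(hi_pnv, on="pnv_code")
    if eb is not None:
        missing = cov_codes - set(eb["pnv_code"])
        if missing:
            raise ValueError(f"EB table missing PNV codes {sorted(missing)}")
        df = df.merge(eb[["pnv_code", "eb"]], on="pnv_code", how="left")
        df["eb_band"] = [classify_eb_band(v) for v in df["eb"]]
    df["cri_all"] = [conservation_risk_index(h, g)
                     for h, g in zip(df["hi_mean"], df["gc_all_pct"])]
    df["cri_pa1"] = [conservation_risk_index(h, g)
                     for h, g in zip(df["hi_mean"], df["gc_pa1_pct"])]
    for name, scheme in schemes.items():
        suffix = "" if len(schemes) == 1 else f"_{name}"
        df[f"class_all{suffix}"] = [classify_risk(h, c, scheme)
                                    for h, c in zip(df["hi_mean"], df["cri_all"])]
        df[f"class_pa1{suffix}"] = [classify_risk(h, c, scheme)
                                    for h, c in zip(df["hi_mean"], df["cri_pa1"])]
    return df


def crisis_pnvs(risk: pd.DataFrame, class_col: str = "class_all",
                vu_cri_floor: float = 3.5, cri_col: str = "cri_all") -> list[int]:
    """PNVs that stand out: all CR and EN, plus VU members above a CRI floor."""
    sel = risk[class_col].isin(("CR", "EN")) | (
        (risk[class_col] == "VU") & (risk[cri_col] > vu_cri_floor))
    return sorted(int(c) for c in risk.loc[sel, "pnv_code"])


def _ols(y: np.ndarray, x: np.ndarray) -> dict:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return {"slope": np.nan, "intercept": np.nan, "r2": np.nan, "p": np.nan, "n": int(x.size)}
    fit = stats.linregress(x, y)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r2": float(fit.rvalue**2), "p": float(fit.pvalue), "n": int(x.size)}


def summary_statistics(risk: pd.DataFrame, class_col: str = "class_all") -> dict:
    """The report-level statistics: OLS of HI on GC, area-GC correlation, class summaries.

    Returns a dict with ``ols_gc_all`` and ``ols_gc_pa1`` (slope, intercept,
    R^2, two-sided p of the slope), ``pearson_area_gc`` (r, p; only when an
    ``area_cells`` column is present), per-class mean and sd of HI, and
    class counts.
    """
    if len(risk) < 3:
        raise ValueError("need at least 3 records for summary statistics")
    hi = risk["hi_mean"].to_numpy(dtype=float)
    out = {
        "ols_gc_all": _ols(hi, risk["gc_all_pct"].to_numpy(dtype=float)),
        "ols_gc_pa1": _ols(hi, risk["gc_pa1_pct"].to_numpy(dtype=float)),
    }
    if "area_cells" in risk.columns:
        area = risk["area_cells"].to_numpy(dtype=float)
        gc = risk["gc_all_pct"].to_numpy(dtype=float)
        ok = np.isfinite(area) & np.isfinite(gc)
        if ok.sum() >= 3 and np.std(area[ok]) > 0 and np.std(gc[ok]) > 0:
            r, p = stats.pearsonr(area[ok], gc[ok])
            out["pearson_area_gc"] = {"r": float(r), "p": float(p)}
        else:
            out["pearson_area_gc"] = {"r": np.nan, "p": np.nan}
    by_class = {}
    for label in CLASS_SEVERITY:
        sub = hi[risk[class_col] == label]
        by_class[label] = {
            "count": int(sub.size),
            "hi_mean": float(np.mean(sub)) if sub.size else np.nan,
            "hi_sd": float(np.std(sub, ddof=1)) if sub.size > 1 else np.nan,
        }
    out["by_class"] = by_class
    if "category" in risk.columns:
        out["by_category"] = {
            str(cat): {"hi_mean": float(np.mean(g)), "hi_sd": float(np.std(g, ddof=1)) if len(g) > 1 else np.nan,
                       "count": int(len(g))}
            for cat, g in risk.groupby("category")["hi_mean"]
        }
    return out
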