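"""Multivariate environmental similarity surfaces (MES) and the environmental bias (EB).

The MES score of a location measures how similar its environmental
conditions are to those of a reference cell set, in terms of a set of
predictor variables V1..Vi. Per variable, with ``f`` the percentage of
reference values strictly below the location's value ``v`` and
``[min, max]`` the reference range:

* ``f = 0``   -> ``100 * (v - min) / (max - min)``
* ``0 < f <= 50`` -> ``2 f``
* ``50 < f < 100`` -> ``2 (100 - f)``
* ``f = 100`` -> ``100 * (max - v) / (max - min)``

The multivariate score is the minimum over variables; it is at most 100 and
negative exactly when some variable falls outside its reference range. Two
surfaces are computed per vegetation type (PNV): MES1 references all cells
of the PNV (how typical is a location of its PNV), MES2 references the
PNV's protected cells (how well do protected areas represent a location).

The environmental bias of a PNV's protected-area network is

    EB = |median(MES1 in PAs) - median(MES1 in PNV)| / MAD(MES1 in PNV)

with the raw (unscaled) median absolute deviation. Significance of the
PA-vs-PNV shift is assessed with a two-sided Mann-Whitney test, Bonferroni
adjusted across the PNVs with a defined EB. Because neighbouring cells are
spatially autocorrelated, cell-level tests overstate the effective sample
size; see the methods note for this pseudo-replication caveat.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, inf
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .rasterstack_io import GridSpec, LayerStack, Raster
from .protection_coverage import PA1, PNVMap

__all__ = [
    "DegenerateReferenceError",
    "ReferenceDistribution",
    "MESSurface",
    "EBResult",
    "variable_similarity",
    "mes",
    "mes_surface",
    "pnv_mes_surface",
    "environmental_bias",
    "eb_table",
    "environmental_coverage",
    "mann_whitney_two_sided",
]


class DegenerateReferenceError(ValueError):
    """Reference sample has max == min; the similarity score is undefined."""


class ReferenceDistribution:
    """Per-variable sorted reference samples for MES scoring."""

    def __init__(self, samples: Sequence[np.ndarray], names: Sequence[str] | None = None):
        self.samples = [np.sort(np.asarray(s, dtype=np.float64)) for s in samples]
        self.names = list(names) if names is not None else [f"v{k}" for k in range(len(samples))]
        for name, s in zip(self.names, self.samples):
            if s.size < 2:
                raise ValueError(f"reference sample for {name!r} needs >= 2 values, got {s.size}")
            if s[0] == s[-1]:
                raise DegenerateReferenceError(
                    f"reference sample for {name!r} is constant ({s[0]}); similarity undefined"
                )

    def __len__(self) -> int:
        return len(self.samples)

    @classmethod
    def from_stack(cls, stack: LayerStack, reference_mask: np.ndarray) -> "ReferenceDistribution":
        if not reference_mask.any():
            raise ValueError("empty reference mask")
        return cls([stack[n].values[reference_mask] for n in stack.names], stack.names)


@dataclass
class MESSurface:
    mes: Raster
    per_variable: LayerStack | None = None


def variable_similarity(v, ref) -> np.ndarray | float:
    """Similarity of value(s) ``v`` to a single-variable reference sample.

    Negative iff ``v`` lies outside the reference range; at most 100.
    Vectorized over ``v``.
    """
    ref = np.sort(np.asarray(ref, dtype=np.float64))
    if ref.size < 2:
        raise ValueError("reference sample needs at least 2 values")
    lo, hi = ref[0], ref[-1]
    if hi == lo:
        raise DegenerateReferenceError("reference sample is constant; similarity undefined")
    v_arr = np.asarray(v, dtype=np.float64)
    # f = percent of reference values strictly below v (ties count as not below)
    f = 100.0 * np.searchsorted(ref, v_arr, side="left") / ref.size
    span = hi - lo
    score = np.where(
        f == 0.0,
        100.0 * (v_arr - lo) / span,
        np.where(
            f <= 50.0,
            2.0 * f,
            np.where(f < 100.0, 2.0 * (100.0 - f), 100.0 * (hi - v_arr) / span),
        ),
    )
    return float(score) if np.isscalar(v) or v_arr.ndim == 0 else score


def mes(cell: Sequence[float], refs: ReferenceDistribution) -> float:
    """Multivariate similarity of one cell: minimum over per-variable scores."""
    cell = np.asarray(cell, dtype=np.float64)
    if cell.size != len(refs):
        raise ValueError(f"cell has {cell.size} values but reference has {len(refs)} variables")
    return float(min(variable_similarity(v, s) for v, s in zip(cell, refs.samples)))


def mes_surface(stack: LayerStack, reference_mask: np.ndarray, target_mask: np.ndarray,
                keep_per_variable: bool = False) -> MESSurface:
    """MES score for every target cell against the reference cells' distribution."""
    grid = stack.grid
    if reference_mask.shape != grid.shape or target_mask.shape != grid.shape:
        raise ValueError("masks must match the stack's grid shape")
    refs = ReferenceDistribution.from_stack(stack, reference_mask)
    out = np.full(grid.shape, np.inf)
    per_var = {}
    for name, sample in zip(refs.names, refs.samples):
        score = np.zeros(grid.shape)
        score[target_mask] = variable_similarity(stack[name].values[target_mask], sample)
        if keep_per_variable:
            per_var[name] = Raster(grid, score, ~target_mask)
        out = np.minimum(out, np.where(target_mask, score, np.inf))
    mes_r = Raster(grid, np.where(target_mask, out, 0.0), ~target_mask)
    return MESSurface(mes_r, LayerStack(per_var) if keep_per_variable else None)


def pnv_mes_surface(stack: LayerStack, pnv: PNVMap, protection: Raster | None = None,
                    reference: str = "pnv", pa_subset: str = "all") -> tuple[Raster, list[int]]:
    """Assemble a whole-grid MES surface PNV by PNV.

    ``reference="pnv"`` builds MES1 (reference = all cells of each PNV);
    ``reference="pa"`` builds MES2 (reference = the PNV's protected cells,
    all PAs or PA1 only per ``pa_subset``). PNVs whose reference is empty or
    environmentally constant are skipped — their cells stay masked — and
    their codes are returned.
    """
    if reference not in ("pnv", "pa"):
        raise ValueError(f"unknown reference {reference!r}")
    if reference == "pa" and protection is None:
        raise ValueError("protection raster required for reference='pa'")
    grid = stack.grid
    values = np.zeros(grid.shape)
    mask = np.ones(grid.shape, dtype=bool)
    skipped: list[int] = []
    for code in pnv.code_set:
        in_pnv = pnv.mask_for(code) & stack.combined_valid()
        if reference == "pnv":
            ref_mask = in_pnv
        else:
            prot_ok = protection.values >= PA1 if pa_subset == "all" else protection.values == PA1
            ref_mask = in_pnv & prot_ok
        if not ref_mask.any():
            skipped.append(code)
            continue
        try:
            surf = mes_surface(stack, ref_mask, in_pnv)
        except DegenerateReferenceError:
            skipped.append(code)
            continue
        values[in_pnv] = surf.mes.values[in_pnv]
        mask[in_pnv] = False
    return Raster(grid, values, mask), skipped


@dataclass
class EBResult:
    pnv_code: int
    median_pa: float
    median_pnv: float
    mad_pnv: float
    eb: float
    p_value: float
    significant: bool = False


def environmental_bias(mes1: Raster, pa_mask: np.ndarray, pnv_mask: np.ndarray,
                       pnv_code: int = 0) -> EBResult:
    """EB of one PNV: |median(MES1_PA) - median(MES1_PNV)| / MAD(MES1_PNV).

    ``p_value`` is the raw two-sided Mann-Whitney p for the PA-vs-PNV shift;
    Bonferroni adjustment across PNVs is applied by :func:`eb_table`. A zero
    MAD leaves EB undefined (NaN).
    """
    if not pa_mask.any() or not pnv_mask.any():
        raise ValueError("pa_mask and pnv_mask must be non-empty")
    if (pa_mask & ~pnv_mask).any():
        raise ValueError("pa_mask must be a subset of pnv_mask")
    ok = mes1.valid
    x = mes1.values[pa_mask & ok]
    y = mes1.values[pnv_mask & ok]
    med_pa = float(np.median(x))
    med_pnv = float(np.median(y))
    mad = float(np.median(np.abs(y - med_pnv)))
    eb = abs(med_pa - med_pnv) / mad if mad > 0 else np.nan
    p = mann_whitney_two_sided(x, y)
    return EBResult(pnv_code, med_pa, med_pnv, mad, eb, p)


def eb_table(stack: LayerStack, pnv: PNVMap, protection: Raster,
             pa_subset: str = "all", alpha: float = 0.05) -> pd.DataFrame:
    """Per-PNV EB with Bonferroni-adjusted Mann-Whitney significance.

    The Bonferroni divisor is the number of PNVs with a defined EB in this
    run, not a nominal total. PNVs without protected cells are reported with
    NaN statistics.
    """
    mes1, _ = pnv_mes_surface(stack, pnv, reference="pnv")
    prot_ok = protection.values >= PA1 if pa_subset == "all" else protection.values == PA1
    rows = []
    for code in pnv.code_set:
        in_pnv = pnv.mask_for(code) & mes1.valid
        in_pa = in_pnv & prot_ok
        if not in_pnv.any() or not in_pa.any():
            rows.append((code, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        r = environmental_bias(mes1, in_pa, in_pnv, code)
        rows.append((code, r.median_pa, r.median_pnv, r.mad_pnv, r.eb, r.p_value))
    df = pd.DataFrame(rows, columns=["pnv_code", "median_pa", "median_pnv", "mad", "eb", "p_raw"])
    n_defined = int(df["eb"].notna().sum())
    df["p_bonf"] = np.minimum(df["p_raw"] * max(n_defined, 1), 1.0)
    df["significant"] = df["p_bonf"] <= alpha
    df.loc[df["eb"].isna(), "significant"] = False
    return df


def environmental_coverage(mes2: Raster, pnv: PNVMap) -> pd.DataFrame:
    """Percent of each PNV's cells with MES2 > 0 (conditions represented in PAs)."""
    from .rasterstack_io import zonal_stat

    df = zonal_stat(mes2, pnv.codes, "percent_where", predicate=lambda v: v > 0)
    return df.rename(columns={"zone": "pnv_code", "value": "ec_pct"})


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

_EXACT_MAX_SPLITS = 20000


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: #(x > y) pairs + half the tied pairs."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney_two_sided(x, y) -> float:
    """Two-sided Mann-Whitney p-value.

    Small samples (up to ~20k label assignments) are handled by exact
    enumeration of all splits of the pooled values, which is valid under
    ties; the p-value is ``min(1, 2 * min(P(U <= u), P(U >= u)))`` over the
    permutation distribution of U. Larger samples use the tie- and
    continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    if comb(n1 + n2, n1) <= _EXACT_MAX_SPLITS:
        pooled = np.concatenate([x, y])
        u_obs = _u_statistic(x, y)
        idx = range(n1 + n2)
        us = []
        for chosen in combinations(idx, n1):
            sel = np.zeros(n1 + n2, dtype=bool)
            sel[list(chosen)] = True
            us.append(_u_statistic(pooled[sel], pooled[~sel]))
        us = np.asarray(us)
        n = us.size
        tol = 1e-9
        p_le = np.count_nonzero(us <= u_obs + tol) / n
        p_ge = np.count_nonzero(us >= u_obs - tol) / n
        return min(1.0, 2.0 * min(p_le, p_ge))
    return float(mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue)
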