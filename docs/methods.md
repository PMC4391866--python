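# Methods

This note documents the models implemented in `pnvgap`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Grids and rasterization

All layers live on a single strict analysis grid (default cell size 900 m,
matching the resolution at which heterogeneous source layers are usually
harmonised for this kind of regional analysis). Two rasters combine only if
their `GridSpec`s are equal; there is no implicit reprojection or
resampling — `resample_to_grid` must be called explicitly (`nearest` for
categorical layers, which never invents codes; `mean` for scores, which
averages the unmasked contributing cells). The coordinate convention is
fixed once: row 0 is the northernmost row, and cell (i, j) has its center
at `origin + ((j+0.5)·cell, −(i+0.5)·cell)`.

Polygon membership of a cell is decided by **cell-center containment**
(strictly inside). The alternative — area-weighted burning — gives smoother
coverage fractions but is harder to verify; cell-center containment is
deterministic, matches common GIS rasterizers, and admits an exact
point-in-polygon brute-force oracle, which the tests use. At 900 m the two
rules differ only along PA boundaries; the coverage index of any PNV more
than a few cells wide is insensitive to the choice.

Nodata propagates: a derived layer is masked wherever any required input is
masked. Rasters are exchanged as ESRI ASCII grids — a plain-text format
every GIS reads — with floats written at 17 significant digits so that
write→read round trips are bit-exact and the generator's recorded checksums
stay valid for the files on disk.

## Protection grouping and geographic coverage

IUCN categories reduce to PA1 = {Ib, II, III, IV} and PA2 = {VI,
unclassified}; an unknown category is an error, never silently defaulted.
Overlapping PAs are resolved by the highest IUCN classification ranking,
interpreted as the category order Ib > II > III > IV > VI > UNC (the IUCN
numbering; the grouping makes only the PA1-vs-PA2 boundary of this order
consequential). Point features and proposed areas are dropped by the
GeoJSON reader. GC is a plain cell percentage; a PNV with no unmasked cells
gets an *undefined* (NaN) GC rather than 0, so that downstream risk ratios
are not fabricated for empty zones. The grouping encodes management
*objectives* only — no assumption about management effectiveness.

## Environmental similarity and bias

The per-variable similarity of a value v to a reference sample follows the
standard multivariate-environmental-similarity construction: with f the
percentage of reference values **strictly** below v (ties count as not
below — a deterministic convention matching the common implementation),

* f = 0 → 100·(v − min)/(max − min)
* 0 < f ≤ 50 → 2f
* 50 < f < 100 → 2(100 − f)
* f = 100 → 100·(max − v)/(max − min)

The multivariate score is the minimum over variables; it is ≤ 100 and
negative exactly when some variable leaves its reference range. A constant
reference sample makes the score undefined and raises a
`DegenerateReferenceError`; the per-PNV surface assembler records such PNVs
as skipped instead of aborting the run. Reference distributions use **all**
cells of the reference region — no subsampling — which is exact and cheap
at the problem sizes this package targets; a seeded subsampling option can
be added behind `ReferenceDistribution` without touching callers, and the
formula itself is isolated in `variable_similarity` so a variant can be
swapped in.

EB uses medians and the **raw** median absolute deviation (no 1.4826
normal-consistency factor): the conventional thresholds for reading EB
(0.5, 1) are calibrated on the raw scale. EB is invariant to joint affine
rescaling of the MES values, and is undefined (NaN) when the MAD is zero.
Significance is a two-sided Mann–Whitney test of MES1 in the PAs against
MES1 in the whole PNV, Bonferroni-divided by the number of PNVs with a
defined EB in the run (not a nominal total). Small samples use exact
enumeration of all label splits (valid under ties; identical samples give
p = 1); large samples use the tie- and continuity-corrected normal
approximation.

**Pseudo-replication caveat.** The test treats cells as independent.
Spatially autocorrelated surfaces violate this: protected cells arrive in
contiguous blocks, the effective sample size is far below the cell count,
and the cell-level test is anti-conservative. On synthetic landscapes the
type-I rate at the nominal 5 % level is at the nominal rate when the
environmental fields are white noise, but inflates severalfold at realistic
correlation lengths. Cell-level EB significance on real (smooth) data
should therefore be read as descriptive, not inferential; the EB magnitude
itself is unaffected.

## Human influence

Conversion: urban or road cells score 100; elsewhere the score is the
cropland percentage. The pressure indicators act only on the non-converted
share — `HI = C + mean(VTI, HPI, AI, LPI)·(100 − C)/100`, applied at cell
level and then averaged per PNV (unweighted over equal-area cells, i.e.
area weighting). This two-step form avoids assuming converted land has zero
biodiversity value.

* **VTI**: 25 points per physiognomy step the observed land cover lies
  below the potential level, on the six-level sequence forest → open
  forest/woodland → bushland/thicket/wooded grassland → grassland → stunted
  bushland → semi-desert; a five-step drop is capped at 100, and observed
  cover at or above the potential level scores 0. The score is averaged
  over four independent observed land-cover maps.
* **HPI**: linear 0→100 over 0–20 persons/km², saturated above — 20/km² is
  the conventional boundary between rangeland and mixed-farming systems.
* **AI**: travel time to the nearest high-density area (> 1000 persons/km²
  or marked settlements) on an 8-connected least-cost surface. A step costs
  the center-to-center distance (√2·cell on diagonals) divided by the
  harmonic mean of the two cells' speeds — half the step spent in each
  cell, which is time-additive and symmetric. Defaults: roads 60 km/h,
  off-road 4 km/h (walking), rivers impassable except where a road crosses
  (a bridge). Rivers and railways are deliberately not transport modes. The
  score falls linearly from 100 at 0 h to 0 at 6 h and is 0 beyond; a
  landscape with no destinations is uniformly remote (AI ≡ 0).
* **LPI**: feed requirement over availability, capped at 1, × 100.
  Requirement sums per-species density × daily dry-matter intake; defaults
  (cattle 6.25, goats and sheep 1.25 kg DM/head/day) follow the
  250 kg tropical-livestock-unit convention at 2.5 % of body weight per
  day, with small stock at 0.2 TLU. Availability is supplied as a layer
  (kg DM/km²/day; synthetic here — a production use would derive it from
  NPP). The phrase "1 − the ratio" that sometimes accompanies this index is
  read as a typographic dash: pressure must *increase* with stocking rate,
  and the ≥ 1 cap only makes sense applied to the ratio itself. The literal
  reading remains available via `HIConfig(lpi_literal_one_minus=True)`.

HI is bounded in [0, 100], never below the conversion score, and monotone
in every indicator; these are tested as invariants, and the travel-time
solver is verified cell-exactly against an independent Dijkstra oracle.

## Conservation risk

CRI = HI_pnv / GC, with GC = 0 giving +∞ when HI > 0 (a fully unprotected,
pressured PNV classifies by its HI bound alone rather than dropping out)
and 0 when HI = 0. Classification applies strict `>` comparisons in
severity order — the rules are nested, so order matters and is tested:
default CR (50, 10), EN (40, 4), VU (20, 2); the alternative
crisis-ecoregion scheme keeps the HI bounds with CRI bounds 25/10/2, and by
construction never assigns a more severe class than the default scheme.
Classification is run with GC from all PAs and from PA1 only; since
GC_PA1 ≤ GC, the PA1 class is never less severe. EB values are banded
HB (> 1), MB (0.5–1), LB (< 0.5) for reporting. The "stand-out" crisis set
is computed as CR ∪ EN plus VU members above a configurable CRI floor, not
hard-coded. Per-category HI summaries are unweighted means across PNVs
(area-weighted versions are directly computable from the returned table).

## The synthetic landscape generator

The generator is a pure function of its config (seed included); every
planted quantity is recorded in `truth` using plain-numpy restatements of
the scoring rules, independent of the pipeline modules, so recovery tests
compare two separate code paths.

* **Environmental fields**: Gaussian-kernel-smoothed white noise,
  standardized per field; the correlation length (`smoothness`, cells) maps
  to the kernel width as σ = (L−1)/2. Kernel-convolved noise was chosen
  over variogram-exact simulation because exact seeding and speed matter
  here and only the presence of realistic autocorrelation does, not its
  precise covariance model.
* **Vegetation**: quantile strata of the first two fields give `n_pnv`
  non-empty, spatially cohesive classes; each class gets an ordinal
  physiognomy 1–6 by the rank of its mean first-field value and a category
  label. This stands in for a mapped PNV product.
* **Protected areas**: axis-aligned rectangles snapped to cell boundaries
  (exact area bookkeeping; shape realism is irrelevant to the statistics
  under test). A candidate with first-field mean at percentile u of the
  candidate distribution is accepted with probability u^(3b) (or
  (1−u)^(3|b|) for negative bias b), so `pa_env_bias` = 0 is placement
  independent of environment and |bias| = 1 a strong preference for one
  environmental tail. Defaults — 60 areas of ~25 cells on a 100×100 grid —
  emulate the density of real networks (order 5–10 PAs per vegetation
  type). IUCN categories are drawn uniformly from {Ib, II, IV, VI, UNC}.
* **Human layers**: population is a sum of Gaussian town kernels (peak
  `pop_peak`, default 5000 persons/km²) over a rural background that scales
  with the peak; urban cells are those above 1000 persons/km². Roads join
  the towns along a minimum spanning tree; one river random-walks north to
  south and acts as a barrier except at road crossings. Cropland fraction
  is `cropland_intensity` times a blend of population saturation and an
  environmental suitability field. Livestock densities are smooth,
  positive, and scaled to the configured species means.
* **Observed land cover**: four independent degraded copies of the PNV
  physiognomy; per cell and map the level steps down by Binomial(4, q)
  with q = `degradation_strength` × population pressure, clipped at
  level 6. The exact clipped-binomial expectation and variance are recorded
  per cell, giving the planted VTI mean and its standard error.

What the generator does **not** emulate: real biogeography, calibrated
population or livestock magnitudes, climate structure, PA shapes, or
multi-river hydrology. Passing recovery tests therefore demonstrates that
the pipeline measures what was planted under controlled conditions — not
that the indices are accurate descriptions of any real region.

## Numerical and testing choices

* Problem sizes: the standard testbed is a 100×100 grid (10⁴ cells) with 8
  PNVs and 6 environmental variables; oracle-equivalence tests run on
  grids up to 20×20 where brute force is exact and instant. The acceptance
  script repeats landscape generation 30 times for the bias sweep; the
  whole script runs in seconds.
* Stochastic recovery checks standardize deviations by the planted
  standard error and apply the 2-SE (5 %) per-comparison criterion with a
  Bonferroni adjustment for the number of simultaneous PNV comparisons;
  deterministic indicators must match to 1e-9 relative.
* Mann–Whitney switches from exact enumeration to the asymptotic
  approximation when the number of label splits exceeds 2·10⁴.
* Degenerate inputs fail loudly: unknown IUCN categories, constant MES
  references, zero feed availability, out-of-range scores, mismatched PNV
  code sets and non-co-registered rasters all raise with context rather
  than defaulting.

## Known limitations

* Cell-level EB inference is anti-conservative under spatial
  autocorrelation (see above); a block-resampling test would be the
  statistically defensible upgrade.
* MES reference distributions are exact empirical distributions; at
  continental scale a seeded subsample would be needed.
* The livestock model ignores species beyond cattle/goats/sheep and treats
  feed availability as given.
* Travel time uses a single off-road speed rather than land-cover-specific
  friction, and the grid is assumed equal-area (no projection handling).
* No tiled/streaming raster processing: everything fits in memory by
  design.
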