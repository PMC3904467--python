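# Methods

## Scope and model

`aridforest` implements a two-track landscape-change analysis.

**Track 1 — climate aridization.** The unit of analysis is the
station-year. Monthly temperature (°C) and precipitation (mm) series
may have gaps at all stations except one reference station. Gap-filling
assumes a time-invariant linear link between each satellite station and
the reference, per variable: one slope/intercept pair per
(station, variable), fitted by OLS over all paired months pooled across
calendar months and years. This is the simplest model consistent with
a dense, physiographically homogeneous station network; it ignores
seasonally varying relationships (a per-calendar-month fit would need
~12× the overlap to be as stable). Filled precipitation is floored at
0 mm. Observed values are never modified, and filled cells carry an
explicit flag.

Annual aggregation uses the calendar year (January–December); a
station-year enters the index tables only when all 12 months are
present after filling. The indexes are

- De Martonne `I_DM = P_annual / (T_mean + 10)` in mm/°C, defined for
  `T_mean > −10 °C`; strictly increasing in P, decreasing in T.
- UNEP `I_UNEP = P_annual / PET_annual`, with PET from the Thornthwaite
  method: heat index `I = Σ_{T_m>0} (T_m/5)^1.514`; exponent
  `a = 6.75·10⁻⁷ I³ − 7.71·10⁻⁵ I² + 1.792·10⁻² I + 0.49239`;
  unadjusted monthly PET `16·(10·T_m/I)^a` mm for `0 < T_m ≤ 26.5 °C`,
  the polynomial `−415.85 + 32.24·T_m − 0.43·T_m²` above 26.5 °C, and 0
  for freezing months; each month scaled by
  `(mean day length/12)·(days in month/30)`, day length from the
  solar-declination sunset-hour-angle formula
  (`δ = 0.409·sin(2πJ/365 − 1.39)`, mid-month day of year, non-leap
  calendar). Latitude must lie in ±66.5° (no polar day/night).

Class boundaries are half-open `[low, high)`. De Martonne: <10 arid,
10–15 semi-arid, 15–20 semi-arid/steppe, 20–24 moderately dry, 24–28
moderately humid, ≥28 humid (the classical scheme). UNEP: <0.05
hyper-arid, 0.05–0.2 arid, 0.2–0.5 semi-arid, 0.5–0.65 dry sub-humid,
≥0.65 humid (the 1992 UNEP drylands scheme). Trends are plain OLS of
the annual index on the year; no significance testing is attempted.

**Track 2 — degradation and clear-cutting.** Rasters are north-up,
square-pixel grids on a projected metric coordinate system, carried in
a lightweight container with NaN as nodata and stored as ESRI ASCII
grids — a georeferenced plain-text interchange format every desktop GIS
reads. Calibration of digital-number imagery is
`L = gain·DN + offset`, dark-object (DOS1) haze subtraction floored at
zero, and top-of-atmosphere reflectance
`ρ = π·L·d² / (ESUN·sin(sun elevation))`. DOS1 was chosen as the
simplest fully testable correction: it is algebraically invertible, so
the tests can verify round-trip recovery to 10⁻⁶.

NDVI pixels with `NIR + RED = 0` become nodata (0/0 carries no
vegetation information). The MSAVI2 discriminant
`(2·NIR+1)² − 8·(NIR−RED)` can go negative only for band values outside
the physical range; it is clamped to 0 before the square root and the
affected pixels are reported. Threshold bins are half-open `[low, high)`
with default breakpoints 0.1 / 0.2 / 0.3 / 0.55. Area per class is
`pixels × pixel_size² / 10⁴` ha; shares are relative to the non-nodata
area, so they always sum to 100%. Two-date relative change must name
its convention explicitly — `relative-to-first` `(A₂−A₁)/A₁` or
`relative-to-second` `(A₂−A₁)/A₂` — because headline rates in this
literature mix both. Zonal aggregation assigns pixels by center
containment, which makes zone partitions exactly additive. Two scenes
of one date are mosaicked by first-valid-pixel-wins (acquisitions
seconds apart need no temporal adjustment).

The transition matrix is oriented columns = earlier date, rows = later
date, matching the bookkeeping of the printed case-study tables this
package re-enters as fixtures (a `transpose()` is provided for the more
common rows-earlier convention). `'-'` cells in re-entered tables parse
as 0 ha. Balances are `losses = column − diagonal`,
`gains = row − diagonal`, `net = gains − losses ≡ total_t2 − total_t1`;
areas are carried at full float precision and rounded (0.1 ha cells,
integer headline balances) only on output.

Ward clustering uses `scipy.cluster.hierarchy` on Euclidean distances.
Indicators are z-scored by default: both are in hectares but total
forest area spans thousands of hectares while annual change spans
hundreds, and unstandardized distances would let size dominate. Cluster
labels are renumbered in order of first appearance down the sorted
commune list, making the assignment deterministic and invariant to
input row order. k defaults to 5, the number of commune types the two
indicators support (small/large stable, afforesting, small/large
declining).

## Synthetic data

The generator module emulates the study conditions, not merely test
plumbing:

- **Climate**: 3 stations, 1961–2009 (49 years). Monthly normals typify
  the lower Danube plain (annual mean ≈ 10.6 °C, ≈ 565 mm). The
  reference station adds Gaussian interannual anomalies (sd 1.2 °C,
  18 mm); satellites are linear transforms of the reference (slopes
  1.05/0.95 for T, 1.1/0.9 for P) plus noise (sd 0.4 °C, 6 mm), giving
  pooled monthly precipitation correlations ≈ 0.96 — above the 0.92 the
  gap-filling method presumes. 8% of satellite months are removed
  uniformly at random (gap structure is otherwise unknown);
  precipitation is floored at 0.
- **Scene**: a blocky four-class landscape (water, bare sand, sparse
  vegetation, dense forest) on 30 m pixels (Landsat TM geometry). The
  second date is drawn per pixel from a transition probability table
  whose default expresses sandy-landscape degradation (forest thinning,
  sparse vegetation destabilizing to sand); the realized pixel-count
  transitions are returned as ground truth. Spectral signatures put the
  class NDVI centres in the intended bins (sand ≈ 0.08, sparse ≈ 0.19,
  forest ≈ 0.84); an optional degraded second-date signature set drops
  the forest NDVI centre to ≈ 0.45, emulating canopy drought stress
  without land-use change. Reflectances are clipped to [0, 1].
- **Communes**: 113 communes in 5 planted groups (40/7/25/16/25) with a
  deliberately small 7-commune afforesting group; centroid separations
  are large relative to the within-group spread (sd 120 ha total, 35 ha
  change), so the planted partition is recoverable exactly.

What the generators do **not** emulate: radiative transfer, clouds and
shadows, topographic illumination, spatial autocorrelation of climate
noise, mixed pixels at class boundaries, and commune groups that
overlap in indicator space. Passing tests therefore demonstrate the
correctness of the arithmetic and the recoverability of planted
structure under the stated conditions — not robustness to real-sensor
artefacts or to ambiguous cluster structure.

## Numerical choices

- OLS via `scipy.stats.linregress`; a constant regression target
  returns slope 0, intercept = mean, r = 0 by convention (avoids 0/0);
  zero predictor variance is an error.
- MSAVI2 squares by multiplication (`d·d`, not `d**2`) so the
  vectorized raster path is bit-identical to a scalar per-pixel
  evaluation.
- Bin and class intervals are half-open `[low, high)` everywhere; a
  value exactly at a breakpoint goes to the upper bin.
- Ward merge tie-breaks follow scipy's deterministic pair ordering;
  combined with sorted-input relabelling this fixes the assignment
  across platforms.
- Index values are reported to one decimal, areas to 0.1 ha, headline
  balances to whole hectares, matching the precision such tables are
  printed at.

## Pipeline and problem sizes

Stages communicate through files (delimited text, ASCII grids,
GeoJSON), so each is independently runnable from the CLI and every
reported number is traceable to a stage output; the consolidated report
carries a provenance block (package version, config hash, seed, input
checksums) sufficient to re-run the identical analysis. The bundled
demo uses a 128×128 scene, 3 stations × 49 years and 113 communes and
completes in seconds; the test suite exercises the full pipeline up to
256×256 scenes. Larger rasters are limited only by memory (all raster
operations are vectorized).

## Known limitations

- Thornthwaite PET is temperature-only and known to underestimate PET
  in windy, dry summers; Penman–Monteith alternatives are out of scope.
- Gap-filling transfers the reference station's anomalies; it cannot
  reproduce purely local extremes at a satellite station.
- The aridity classifications at band edges depend on the half-open
  convention; values printed at one decimal may sit exactly on a
  boundary.
- Polygon land-use inputs are supported only after rasterization; the
  geometric-intersection path for polygon layers is not implemented.
- Zonal statistics count a pixel in every zone containing its center;
  overlapping zones double-count by design.
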