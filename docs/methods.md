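# Methods

`cumrisk` builds a cumulative environmental-risk composite indicator on a
regular metric lattice (the *referent grid*) from four risk-factor
dimensions — soil, air, water and noise — and quantifies how the
construction choices (spatialization, exposure transformation,
rank-based standardization) shape the resulting hotspot map.

## 1. Model and procedure

### 1.1 Referent grid and spatialization

All layers are discretized onto a grid of square cells (default side
1000 m) indexed row-major from the top-left, each cell a half-open square
so shared edges are never double-counted. Coordinates are planar metric;
a projected CRS is assumed upstream and no geodesy is performed.

- **Surface-ratio aggregation** transfers rasters between misaligned
  supports. *Intensive* quantities (concentrations, Lden) take the
  overlap-area-weighted mean of valid source cells; *extensive*
  quantities (emissions, population counts) are split proportionally to
  overlap area, which conserves totals exactly. Because both grids are
  axis-aligned, overlap areas factor into products of 1-D interval
  overlaps and the whole operation is two matrix products — exact, not
  sampled.
- **Zone rasterization** assigns each cell the overlap-area-weighted
  mean of the polygon attribute (used for water-distribution-unit scores
  and district emission densities). District emission totals are
  converted to areal densities (t yr⁻¹ km⁻²) before rasterization so
  the cell value does not depend on district size.
- **Buffer partitioning** converts a point inventory of potentially
  contaminated sites into a proximity density: per cell, the sum over
  sites of area(cell ∩ disc(site, r))/area(cell), with r = 300 m by
  default. Overlapping buffers from distinct sites are *summed*, not
  unioned — the quantity is a site density, and a cell ringed by three
  sites should score higher than one near a single site. Cells far from
  all sites score a valid 0 (zero measured exposure), not nodata.
- **Point interpolation** estimates topsoil concentrations at cell
  centres from scattered samples. Default is inverse-distance weighting
  (power 2, exact-hit rule within 1e-9 m); ordinary kriging with an
  isotropic exponential variogram fitted by weighted least squares on
  the empirical variogram is available (`method="ordinary_kriging"`).
  Duplicate sample locations are averaged (the kriging system is
  singular otherwise) with a warning.

**Zero vs nodata.** "No measurement possible" is nodata; "measured or
derived zero exposure" is a valid 0. The distinction drives background
handling during standardization.

### 1.2 Exposure transformation

- **Soil concentration**: a single-pathway (soil ingestion) screening
  dose, ADD = C·IR·EF/BW (mg kg⁻¹ day⁻¹), divided by the oral reference
  dose to give a hazard quotient HQ = ADD/RfD; HQs are summed across
  pollutants assuming independence of action (no target-organ grouping —
  a deliberate screening simplification), and the cellwise **maximum
  over age classes** is retained. The per-age-class combination is a
  genuinely open design point; the maximum is the conservative screening
  choice, and the function also accepts precomputed ADD fields so richer
  multimedia transfer models can be plugged in.
- **Air concentration**: Σ over pollutants of (annual mean
  concentration / air-quality standard).
- **Emission score**: three components — total emissions, cancer-weighted
  and respiratory-non-cancer-weighted emissions — each min–max scaled to
  [0, 1] over valid cells and averaged. Equal weights are the default;
  the relative weighting of the three components is exposed because no
  canonical choice exists. A constant component (min = max) contributes
  0 with a warning.
- **Water**: the multi-year mean count of drinking-water threshold
  exceedances per distribution unit (4 years by default). Concentrations
  below thresholds contribute nothing, so most units score exactly 0.
- **Noise**: the Lden level itself, passed through; cells without a
  noise estimate stay nodata.
- **Equity combination**: air = concentrations + emissions and soil =
  proximity + topsoil HQ are combined by standardizing each component
  (so both enter with identical mean and range) and summing, giving a
  combined field in [0, 2]. The combined field is then *re-standardized*
  before entering the four-way composite; this is the only reading under
  which all four dimensions satisfy the equity constraint (equal mean
  and range) simultaneously.

### 1.3 Rank standardization under the equity constraint

Both transforms depend only on the rank order of the values, so every
dimension enters the composite with the same score multiset when there
are no ties:

- **Percentile rank**: Hazen plotting position s(r) = (r − 0.5)/n,
  strictly inside (0, 1). The Hazen position was chosen for its exact
  symmetry (mean exactly 0.5 for distinct values); the source framework
  fixes no specific plotting position.
- **Normal score**: the Blom approximation of the expected standard
  normal order statistic, z(r) = Φ⁻¹((r − 0.375)/(n + 0.25)), rescaled
  to [0, 1] as s(r) = (z(r) − z(1))/(z(n) − z(1)). The rescaling is
  anchored at the rank-1 and rank-n scores of the full sample — not at
  the realized min/max — so a tied bottom group lands strictly above 0.
  Exact order-statistic expectations (by numerical integration) are kept
  in the test oracle only; Blom is accurate to well under 5e-3 on the
  [0, 1] scale.

**Background and ties.** Cells with no measurement, plus cells with
exactly zero exposure in hotspot-type dimensions (water, noise, site
proximity), are *background*. Background cells occupy the bottom ranks
1..k; concentration-type dimensions (air, soil HQ, emissions) keep zeros
as ordinary values. Any tie group occupying integer ranks a..b receives
the **mean of the transformed scores** of those ranks. On the percentile
scale this equals transforming the averaged rank (the transform is
linear in rank); on the normal-score scale averaging the transformed
ranks is what makes the score sum — hence the field mean — invariant to
tie structure: the z-grid sums to zero by antisymmetry, so every
standardized field has mean exactly 0.5 regardless of how much
background it carries. Ranks always sum to n(n+1)/2; background cells
are never dropped, so n is the full cell count.

### 1.4 Composite, aggregation, diagnostics

- **Composite** = cellwise sum of the four standardized sub-indicators,
  in [0, 4]. Cells background in every dimension remain valid, holding
  the summed background scores.
- **Population-weighted block aggregation**: each cell is assigned to
  exactly one census block by largest polygon–cell overlap (fractional
  splitting is a listed future option); the block value is
  Σ popᵢ·compᵢ / Σ popᵢ. Blocks with zero total population fall back to
  the unweighted mean and are flagged rather than dropped.
- **Correlation structure**: pairwise Spearman rank correlation over
  jointly valid cells (ties averaged), computed on standardized fields
  by default with a switch for raw fields.
- **Top-tail contributions**: cells strictly above the empirical
  q-quantile of the composite (q = 0.9 default; ties at the threshold
  excluded); per dimension, the mean over selected cells of the cellwise
  share (score/composite) × 100. Share-then-average preserves the
  sum-to-100 property exactly; pooled Σscore/Σcomposite is available via
  `pooled=True`.
- **Sliding-window slope**: OLS slope of score vs raw value in a centred
  window (default 51) along the sorted transform curve; a low slope near
  the maximum flags extremum smoothing.
- **Heteroscedasticity ratio**: background score ÷ smallest
  non-background score. 1 means the background assignment created no
  gap; small values flag a large gap.
- **Distribution fit ranking**: uniform/normal/logistic fitted by
  moments and ranked by the Kolmogorov–Smirnov statistic
  (Anderson–Darling also reported).

## 2. Synthetic regions and what they do (not) emulate

The generator produces every raw layer of the study inventory with known
ground truth, at defaults emulating the study conditions at roughly one
tenth of the regional area: a 60 km × 40 km domain (40×60 one-km cells),
~800 topsoil sample points and ~40 contaminated sites (densities matched
to the regional inventory of ~8000 points and 322 sites over
23,547 km²), 30 districts, 40 water units, 150 census blocks, and noise
values on exactly 10% of cells.

- Background concentration surfaces are smoothed white noise (Gaussian
  blur of seeded noise, 5 km length scale) — cheap, seedable spatial
  autocorrelation, not exact Gaussian-process draws.
- Hotspots are additive Gaussian bumps scaled by the background mean;
  amplitudes are drawn in [1.2, 1.6] × the configured floor and radii in
  [2.5, 4.5] km so the discretized surface still exceeds mean × amplitude
  at the centre cell after cell-centre smoothing. Optionally the first
  hotspot of several dimensions shares one location
  (`n_shared_hotspot_dimensions`) to create a known multi-stressor cell.
- Sites cluster along a randomly oriented linear axis (±2 km lateral
  scatter), mimicking an industrial corridor.
- Noise is a corridor pattern: Lden = 55 + 20·exp(−d/1500 m) dB(A) (plus
  1 dB noise, clipped to 55–75) on exactly round(f·n) cells nearest to
  three random polylines; everything else is nodata.
- Water exceedance counts are zero-inflated Poisson (75% structural
  zeros, λ = 1.2 else); hotspot units get λ = the hotspot amplitude.
- Population is lognormal over a 200 m grid with spatial structure
  (median ≈ 3 per 0.04 km² cell, heavy right tail).
- Polygon layers are random Voronoi tessellations clipped to the extent
  (exact tiling). Seed points keep a minimum separation (2.2 × cell
  size, capped by the packing limit) so every census block is the
  largest-overlap winner in at least one cell.

What the generator does **not** emulate: atmospheric dispersion or noise
propagation physics, geochemical covariance between metals, temporal
structure, population mobility, or calibration to any real region's
statistics. Passing tests therefore demonstrate correctness of the
*construction machinery* and the *qualitative* transform effects, not
predictive fidelity for real exposure data.

The tail-contrast pair (`generate_tail_contrast_pair`) supplies a
lognormal(0, 1.5) vector (heavy right tail) and a 2·Beta(2, 2) vector
(bounded, light-tailed) for transform-sensitivity experiments.

## 3. Numerical choices

- Equity range checks: tolerance 1e-9. Composite decomposition is exact
  to 1e-12 (plain summation).
- Aggregation treats overlaps below 1e-12 × cell area as empty;
  zone rasterization requires coverage above 1e-9 × cell area.
- Buffer discs are shapely polygons with 128 segments per quadrant
  (relative area error ~2.5e-5).
- IDW exact-hit threshold 1e-9 m. Kriging: nugget allowed, bins up to
  the 0.7 distance quantile, weights √count; duplicate points averaged.
- Degenerate inputs fail loudly: all-background fields, all-tied ranks,
  grids of mismatched geometry, negative counts, non-positive reference
  values.
- Contribution threshold is strict (>) at the empirical quantile; ties
  at the threshold are excluded.

## 4. Known limitations

- Because both standardizations are pure rank maps, a dimension's
  *marginal* distribution (e.g. tail weight) has no effect on its
  standardized score multiset in the absence of ties: for tie-free
  fields the two transforms redistribute top-decile contributions
  essentially symmetrically across dimensions. Transform sensitivity of
  contributions is driven by tie and background structure — where ties
  sit (bottom vs top of the distribution) decides which dimensions gain
  under which transform. The slope and heteroscedasticity diagnostics
  capture this directly; see the test suite.
- On the percentile scale the heteroscedasticity ratio has the closed
  form k/(2k + 1) for k background cells — it *increases* toward 1/2
  with the background fraction for every n. The monotone *decrease* of
  the background gap ratio holds on the normal-score scale at large cell
  counts (the regional scale, ~2×10⁴ cells), which is what the
  acceptance check exercises.
- The ingestion dose model is single-pathway; no dermal/inhalation
  routes, no food-chain transfer, no noise exposure–response conversion.
- Cell-to-block assignment is whole-cell (largest overlap); fractional
  splitting is not implemented.
- No reprojection: all inputs must already share one planar metric CRS.
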