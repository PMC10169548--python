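# Methods

## The correction model

`rfmscale` treats a reduced-form air-quality model's speciated PM₂.₅ bias
as multiplicative and regionally coherent: within a chosen scope the model
field is assumed to differ from reality mainly by a species-specific
factor. The estimator is the ratio of means over the scope's observation
pairs, SF = mean(O)/mean(P), not the mean of per-pair ratios — the two
differ whenever bias correlates with concentration, and the ratio of means
is the one that exactly zeroes the scope's aggregate bias (NMB) after
application. Three algebraic consequences follow and are enforced by
tests: post-scaling NMB over the defining scope and observation set is 0;
a scope-uniform factor leaves Pearson R² unchanged; per-cell scaling
against a reference reproduces that reference exactly (NME = 0, R² = 1,
Improvement Ratio 0). These are properties of the estimator, not evidence
of skill — skill claims require observations not used for scaling.

Scopes trade bias removal against variance and overfitting. Nationwide
uses all pairs but cannot fix regionally opposed biases; per-state and
per-city restrict pairs by cell-centroid membership in the region polygon;
k-nearest-monitors gives every cell its own factor from the k monitors
closest to its centroid (planar Euclidean distance, ties at the k-th
distance broken by ascending monitor id); per-grid-cell scaling adopts the
satellite value's ratio cell by cell, which is exact against that
reference but inherits all of its error. A state with no monitor for a
species borrows a donor state's SF — either from an explicit fallback map
or, with `auto_fallback`, the nearest state (centroid distance) that has
one.

Because the underlying model is linear in emissions, sector fields sum to
the total field, and one cell-and-species factor scales all sectors alike;
scaling therefore commutes with the sector decomposition, which is what
licenses recomputing percent source contributions from scaled fields.

## Parameters that matter

| parameter | default | units | notes |
|---|---|---|---|
| size ladder | 288, 96, 48, 24, 12, 4, 2, 1 | km | allowed cell edges; adjacent ratios 3,2,2,2,3,2,2 |
| population threshold | 40,000 | people | cell above it is subdivided |
| density threshold | 500 | people/km² | second split trigger; a conventional urban-density cutoff, configurable |
| urbanicity classes | 1–4 urban, 12 semi-urban, ≥24 rural | km | pure function of cell size |
| completeness minimum | 274 | days | 75% of a 365-day schedule for an annual mean |
| k (nearest monitors) | 5 | — | |
| city population minimum | 350,000 | people | urbanized areas eligible for city scaling |
| NMB benchmarks | ±10 goal, ±30 criteria | % | strict inequalities at the boundary |
| NME benchmarks | 35 goal, 50 criteria | % | an NME of exactly 35 meets criteria only |

## The synthetic scenario

The generator emulates the statistical structure of a national
bias-correction study so the pipeline is testable against known truth.

*Population and grid.* Gaussian city clusters (default 20, lognormal
populations with median 4×10⁵) over a 2 people/km² rural background on a
576 × 576 km planar domain. The grid splits recursively wherever either
threshold is exceeded; under the defaults this yields ≈5,500 cells with
roughly 80/10/10 urban/semi-urban/rural population shares.

*Truth fields.* Per sector, a sum of isotropic exponential kernels
w·exp(−d/L) around source points — road transport at city centres
(L = 25 km), power plants and industry scattered (L = 50–60 km),
agriculture broad (L = 120 km) — weighted per species: agriculture is
ammonium-heavy, power plants emit sulfate only, transport is
nitrate-heavy. Cell truth is the zonal mean of the 1-km truth raster, so
model, monitors and satellite are mutually consistent by construction.
The overall amplitude is set so domain means land at realistic
0.6–1.3 μg/m³ annual levels.

*Model bias.* model = truth × β(species) × ε, with β defaulting to 0.52
(pSO₄), 1.08 (pNO₃), 1.69 (pNH₄) — the under-sulfate / over-ammonium
pattern typical of linearised chemistry, giving zero-noise NMB of exactly
−48%, +8%, +69% — and ε a spatially correlated (50 km) lognormal field
with median 1 and log-sd 0.15, drawn once per species and shared across
sectors so linearity is preserved exactly.

*Monitors.* Per species, 150 cells drawn with probability proportional to
population (plus a floor of one), a monitor placed uniformly inside each;
365 daily values = cell truth × iid lognormal day factors (median 1,
log-sd 0.2). Annual means therefore converge to cell truth as noise
shrinks, with a small positive bias exp(σ²/2) ≈ 1.02 inherited from the
lognormal mean.

*Satellite.* Total truth per species on the 1-km raster times a smooth
median-1 lognormal error (log-sd 0.05) — a noisy but monitor-consistent
rendering of truth, standing in for an AOD-derived product fused with
ground data.

What passing tests on this scenario show: the estimator, its algebra, the
geometry, and bias recovery under the stated noise model. What they do
not show: performance under real-world error structure — additive and
heteroscedastic monitor error, satellite retrieval artifacts correlated
with terrain, model error that is not multiplicative, monitor siting
bias. The generator's multiplicative, smoothly correlated errors are the
friendliest case for a ratio estimator.

## Numerical conventions

- Planar equal-area coordinates in km throughout; cell bounds are
  half-open [x0,x1)×[y0,y1), so every point, monitor and raster-pixel
  centre belongs to exactly one cell. Region membership of a cell is by
  centroid; a centroid exactly on a shared region boundary goes to the
  lexicographically first region id.
- Zonal regridding uses the pixel-centre rule with summed-area tables;
  an area-weighted alternative was considered and rejected as the default
  because the centre rule is deterministic, exact to test by brute force,
  and indistinguishable in practice at a 1-km pixel / ≥1-km cell ratio.
- Degenerate inputs get sentinels, not silent zeros: R² with zero
  variance is NaN ("undefined"), normalized metrics with ΣO = 0 are NaN,
  an Improvement Ratio with zero denominator is 0 if the scaled value
  matches the observation and +inf otherwise, and both are excluded from
  the percent-improved summary with a logged count.
- SFs must be positive and finite; a scope whose predictions sum to zero
  raises rather than emitting an infinite factor.
- All randomness flows from one seed through named `SeedSequence` spawns;
  scenario generation, pipeline runs and manifests are bit-reproducible.

## Open choices made here

- The density threshold's default (500 people/km²) is a deliberate,
  configurable choice of a conventional urban cutoff; grid construction
  is driven primarily by the 40,000-person threshold in the default
  scenario.
- Multiple monitors in one cell each contribute their own pair (the
  cell's prediction is reused); averaging per cell is the configurable
  alternative.
- k-NN factors weight the k monitors equally; distance weighting was
  left out to keep the estimator the plain ratio of means.
- City polygons are kept disjoint and non-city cells stay unscaled and
  flagged; city-scheme evaluation covers scaled cells only, since the
  rest of the domain was never corrected.
- Percent source-contribution changes are reported in percentage points
  (scaled% − unscaled%), which sum to zero across sectors per region.

## Problem sizes

The default scenario (≈5,500 cells, 450 monitors, 165k daily records,
three 576×576 rasters) generates in ~3 s; the full multi-scheme pipeline
runs in ~15 s and the acceptance script in ~10 s on one CPU. These sizes
were chosen as the smallest at which the grid exhibits its full size
ladder and every scheme has enough pairs per scope to be meaningful.

## Known limitations

- The correction is annual-mean and multiplicative; it cannot repair
  errors in spatial pattern within a scope (visible as unchanged R² under
  uniform scaling) or in temporal structure.
- Grid-cell scaling against a satellite product transfers that product's
  biases one-for-one; it is a re-gridding of the reference, not an
  independent estimate.
- Benchmarks used for classification were developed for daily PM₂.₅
  model evaluation; no annual-specific benchmarks exist.
- The synthetic satellite is built from the same truth as the monitors,
  mirroring the circularity of real monitor-fused products: evaluation
  against one source after scaling with the other is not independent.
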