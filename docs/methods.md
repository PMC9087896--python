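# Methods

This note documents the models implemented in `coastveg`, the choices made
where the procedure left room, and what the synthetic test bed does and does
not establish.

## Vegetation cover: NDVI and the dimidiate pixel model

NDVI is computed per pixel as `(ρ_nir − ρ_red)/(ρ_nir + ρ_red)` on surface
reflectances and clamped to [−1, 1]. Pixels with a zero band sum are masked
NoData: a zero-sum reflectance pair is non-physical and the ratio is
undefined.

The dimidiate pixel model treats each pixel as a linear mixture of a pure
bare-soil endmember and a pure full-canopy endmember, so fractional
vegetation cover is

    FVC = (NDVI − NDVI_soil) / (NDVI_veg − NDVI_soil)

clamped into [0, 1] (not masked) because NDVI values beyond the endpoints
are expected in real scenes and a full-coverage FVC map is wanted.  Three
endpoint sources are supported:

- **fixed** constants, default `(0.06, 0.6)` — a standard choice for
  temperate coastal scenes and the default analysis configuration;
- **quantile**: the 5%/95% (configurable) quantiles of the scene's finite
  NDVI values, linearly interpolated on the sorted sample.  The cumulative
  frequency convention is not standardised; linear interpolation was chosen
  because it is `numpy`'s default and exactly testable;
- **extremes**: extrapolation from a known (NDVI_min, NDVI_max) pair and the
  FVC values they correspond to, using the published endpoint equations
  verbatim.  This path exists for completeness and is never used by the
  default pipeline.

FVC classes use half-open bins `[0,0.2) [0.2,0.4) [0.4,0.6) [0.6,0.8)` with
a closed top bin `[0.8,1]`, labelled BL&W, L-FVC, SL-FVC, M-FVC, H-FVC.
The class ranges are conventionally written with shared boundaries
("0–0.2", "0.2–0.4"); lower-inclusive binning with a closed top is the
convention here so every value in [0, 1] receives exactly one class.

Class-area tables multiply pixel counts by the cell area; proportions are
taken over non-NoData pixels only, so scenes with different water/cloud
masks have different totals by construction.

## Land-surface temperature: single-band radiative transfer

The thermal chain is

1. `L_sen = gain·DN + offset` (linear absolute calibration),
2. `B(T_s) = ((L_sen − L_u)/τ − (1 − ε)·L_d)/ε` (inversion of the thermal
   radiative transfer equation),
3. `T_s = K2 / ln(K1/B + 1)` (inverse Planck relation for the band).

Parameters, units and defaults:

| parameter | meaning | unit | default |
|---|---|---|---|
| gain, offset | DN → radiance calibration | W·m⁻²·sr⁻¹·µm⁻¹ (per DN / absolute) | per sensor profile |
| K1, K2 | band Planck constants | W·m⁻²·sr⁻¹·µm⁻¹, K | per sensor profile |
| τ | band transmissivity | — | 0.85 summer / 0.95 winter |
| L_u, L_d | up-/downwelling path radiance | W·m⁻²·sr⁻¹·µm⁻¹ | 1.81/2.99 summer, 0.60/1.05 winter |
| ε_v, ε_s | canopy / bare emissivity | — | 0.986 / 0.970 |

Sensor profiles ship the public handbook constants of the three Landsat
thermal generations (TM band 6, ETM+ band 6, TIRS band 10).  Atmospheric
terms are per-scene configuration, as they would come from an atmospheric
correction calculator; they are never estimated.

Emissivity defaults to a two-value scheme keyed on the FVC grid the
pipeline has already computed (ε_v where FVC ≥ 0.5, ε_s elsewhere), with a
constant-ε override.  This is deliberately the most minimal scheme
consistent with the pipeline's inputs; an NDVI-threshold scheme with a
mixed-pixel ramp would be a drop-in refinement.

Numerical conventions: all temperatures are kelvin internally, with °C only
at the reporting boundary; nonpositive surface radiance (possible when
`L_sen < L_u`) masks the pixel rather than raising; retrieved temperatures
outside a plausibility window (default [220, 340] K) are likewise masked so
batch runs survive degenerate pixels.

Station validation matches each station to the pixel containing its
coordinates (point sampling — no footprint averaging; the matching rule for
real 30 m pixels is ambiguous and point sampling is the assumption least
likely to smear errors) and reports MAE, RMSE and the matched count.

## Heat-island zoning and the URI

The LST grid is split into five zones around the scene mean μ with
half/full standard-deviation offsets: HTZ above μ+std, then SHTZ, MTZ,
SLTZ with upper-inclusive boundaries, and LTZ at or below μ−std.  The
bottom closure is made inclusive so the five intervals tile the real line.
The standard deviation uses the population (divide-by-n) convention — the
statistic describes the whole scene, not a sample — which also makes the
boundary tests exact.  A constant grid degenerates to all-MTZ with a
warning rather than an error.

Because the zone boundaries are affine in (μ, std), the classification is
invariant under positive affine transforms of the LST values; min–max
normalisation is provided for display parity but the classification path
consumes raw kelvin.

The urban-heat-island ratio index is

    URI = (1/(100·m)) Σ ωᵢ pᵢ ,  m = 5,  ω = (5,4,3,2,1) hottest→coldest,

with pᵢ the zone area percentages over the same non-NoData pixel universe
as the area tables.  URI ranges over [0.2, 1.0] when the proportions sum
to 100 and is strictly monotone under moving area to a hotter zone.

## Coastline-distance zoning and the fishnet regression

Distance to the coast is the Euclidean distance to the nearest point of the
coastline polyline, in the scene's projected CRS.  Zones: offshore ≤ 10 km
< middle ≤ 25 km < inland, read literally from the band definitions.

The fishnet is a square grid snapped to the raster origin.  The cell length
must be an integer multiple of the raster cell: block aggregation is then
exact and testable against brute-force averaging.  (A 100 m fishnet over
30 m pixels, as produced by GIS tooling with partial-overlap weighting, is
not representable this way; the pipeline snaps a requested length to the
nearest valid multiple.)  Cells keep the mean FVC and mean LST over their
valid pixels; cells with fewer than 50% valid pixels (configurable) are
dropped so near-coast slivers cannot dominate the fits.  Each retained cell
is assigned a zone from its centre distance — one representative point is
adequate for 100–400 m cells against multi-km zone widths.

Per zone, mean LST is regressed on mean FVC by ordinary least squares
(`scipy.stats.linregress`); slope (K per unit FVC), intercept, r², the
slope standard error and the cell count are reported.  Fits require ≥ 3
cells and nonzero FVC variance.  Kelvin vs Celsius only shifts the
intercept, never the slope.

## The synthetic scene generator

The generator emulates a coastal hilly landscape: sea west of a
piecewise-linear coastline, mountain forest nearest the coast, an urban
belt, then agriculture and bare land inland.  Land-cover classes are
allocated by ranking land pixels on coast distance plus Gaussian mixing
noise (sd 6 km), which preserves the gradient while giving every distance
band a mix of cover types — without the mixing, within-zone FVC variance
would be too small to support the zonal regressions.

True FVC is drawn per class from a clipped normal (summer means: forest
0.88, agriculture 0.68, urban 0.18, bare 0.06).  In winter the deciduous
fraction of the forest (default 0.6) drops to a leaf-off mean of 0.30 and
cropland falls to 0.25, so winter scenes have strictly lower mean FVC.

True LST is constructed as a coastal-zone-dependent linear response,

    LST = a(zone) + b(zone)·FVC + N(0, 0.5 K),

with summer slopes (−3, −4.5, −6) K/FVC for (offshore, middle, inland) —
vegetation cooling steepening away from the moderating sea — and near-zero
winter slopes (0.3, −0.2, 0.8).  These construction values double as the
recovery targets of the regression tests.

**Manufactured consistency.** Bands are the exact inverse of the analysis
chain: NDVI is chosen so the dimidiate inversion with endpoints (0.06, 0.6)
returns the true FVC; the reflectance pair encodes that NDVI at a fixed
band sum of 0.5; thermal DN comes from true LST → Planck radiance → forward
radiative transfer → inverse calibration with 16-bit quantization.  The
stored true LST is recomputed from the *quantized* DN, so the analysis
chain recovers it to floating-point error rather than to a quantization
tolerance.  Consequences to keep in mind:

- round-trip tests are sharp (1e-9 FVC, 1e-6 K) but certify only that the
  inversion is the exact inverse of the forward construction — they say
  nothing about atmospheric-correction error, emissivity error, sensor
  noise or mixed-pixel effects in real archives;
- station residuals on synthetic scenes equal the injected station noise
  exactly, so MAE/RMSE validate the noise model and the matching logic,
  not retrieval skill;
- the generator does not simulate clouds, scan-line gaps, topographic
  illumination, or realistic radiative transfer (explicit non-goals).

Default scene: 160×220 cells at 200 m (44 km × 32 km, ≈1400 km²), which
spans all three coastal zones at desk scale; 15 stations with 2 K noise.
The regression-recovery suites use 48×220 scenes (100 replicates) and the
round-trip suite 128×128 — sizes chosen so the whole test suite runs in
seconds while every zone still holds thousands of fishnet cells.

Determinism: one `numpy` Generator seeded from the spec drives all draws,
so identical specs give bit-identical scenes and distinct seeds give
distinct scenes.

## The packaged area table

`data/published_class_areas.csv` carries the published per-scene class areas (km²)
for ten scenes (five summer, five winter, 2000–2020) in both the FVC and
the temperature segmentation.  `summarize_published_areas` recomputes the
class proportions (rounded to 2 decimals only at this reporting boundary)
and the URI from the LST proportions.  Note the URI recomputed from these
areas (≈0.60–0.62 in summer) is the area-weighted definition above; URI
figures quoted elsewhere for the same scenes can differ if a different
pixel universe (e.g. built-up area only) was used, which the area table
alone cannot resolve.

## Statistical check conventions

The zonal-recovery suite asserts that the *replicate-mean* fitted slope
lies within three (mean) standard errors of the construction value.  With
100 replicates and two zones, asserting every single fit within 3 SE would
fail by chance in roughly half of all runs even for a correct,
unbiased estimator; the mean-slope criterion tests the same property
without that false-alarm rate.  The inland-steeper-than-offshore ordering
is asserted per replicate (≥ 95 of 100), as a directional property should
be.

## Known limitations

- Raster I/O is plain-text ESRI ASCII grid with a `.prj` sidecar; there is
  no GeoTIFF reader/writer, and CRS handling is an identifier string match,
  not a datum-aware transform.
- The emissivity scheme is a two-value gap-fill, not a calibrated product.
- The fishnet requires integer pixel blocks; partial-overlap weighting is
  not implemented.
- Zone assignment uses cell centres; cells straddling a zone edge are not
  split.
- The per-cover-type NDVI_veg refinement (endpoint per land-use class) is
  out of scope; one endpoint pair serves the whole scene.
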