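# coastveg

A raster analysis pipeline for studying how vegetation cover shapes the
urban thermal environment of a coastal city, built around four standard
remote-sensing methods and a synthetic-scene test bed with known ground
truth.

**Who it is for.** Urban-climate and vegetation-ecology analysts working
with Landsat-like multiband scenes (red/NIR reflectance plus a thermal
band) who want the full chain — vegetation cover, land-surface
temperature, heat-island zoning, and coastline-distance stratified
regression — as reproducible, tested library code rather than a GIS
click-path.

## The methods

1. **Fractional vegetation cover (FVC)** by the dimidiate pixel model:
   each pixel is a linear soil/vegetation mixture, and
   `FVC = (NDVI − NDVI_soil)/(NDVI_veg − NDVI_soil)` with endpoints either
   fixed (default 0.06/0.6) or scene quantiles (5%/95%).  FVC is classified
   into five 0.2-wide classes from bare-land-and-water (BL&W) to high FVC
   (H-FVC).
2. **Land-surface temperature (LST)** by single-band radiative transfer:
   DN → radiance by linear calibration, inversion of
   `L_sen = (ε·B(T_s) + (1−ε)·L_d)·τ + L_u` for the surface blackbody
   radiance, then the inverse Planck relation `T_s = K2/ln(K1/B + 1)`.
   Retrievals are validated against station records with MAE/RMSE.
3. **Heat-island zoning** by the mean–standard-deviation method (five
   zones, HTZ…LTZ, at ±0.5 and ±1 std around the scene mean) and the
   **urban-heat-island ratio index** `URI = (1/(100·5)) Σ ωᵢpᵢ` with zone
   weights ω = 5…1 hottest→coldest; URI ∈ [0.2, 1].
4. **Coastline-distance zonal regression**: a fishnet grid aggregates mean
   FVC and mean LST per cell; cells are stratified into offshore (≤10 km),
   middle (10–25 km) and inland (>25 km) bands by distance to the
   coastline, and mean LST is regressed on mean FVC per band by OLS.  The
   slope (K per unit FVC) measures the vegetation cooling effect.

A synthetic-scene generator (`coastveg.scene_synth`) manufactures coastal
landscapes — sea, near-coast mountain forest, an urban belt, inland
agriculture — whose bands are the exact inverse of this analysis chain, so
every stage is testable against known truth without external data.  See
`docs/methods.md` for the model details and design choices.

## Worked example

```python
from coastveg import (LandscapeSpec, generate_scene, generate_stations,
    compute_ndvi, compute_fvc, DimidiateEndpoints, classify_fvc,
    class_area_table, emissivity_from_fvc, retrieve_lst, validate_lst,
    classify_lst_zones, build_fishnet, fit_all_zones)
from coastveg.heat_island import uri_from_zone_table

spec = LandscapeSpec(seed=42, date="2020.06")   # 160×220 cells at 200 m, summer
scene, truth = generate_scene(spec)

ndvi = compute_ndvi(scene)
fvc = compute_fvc(ndvi, DimidiateEndpoints(0.06, 0.6))
print(class_area_table(classify_fvc(fvc))[["class", "area_km2", "proportion_pct"]]
      .round(2).to_string(index=False))

lst = retrieve_lst(scene, emissivity_from_fvc(fvc), truth.atmosphere)
val = validate_lst(lst, generate_stations(truth, n=15, noise_sd=2.0, seed=7))
print(f"station validation: MAE={val.mae:.2f} K  RMSE={val.rmse:.2f} K  n={val.n}")

zones, params, zone_table = classify_lst_zones(lst)
print(f"URI={uri_from_zone_table(zone_table).uri:.4f}")

fishnet = build_fishnet(fvc, lst, truth.coastline, cell_length=200.0)
print(fit_all_zones(fishnet)[["zone", "slope", "r2", "n"]].round(3).to_string(index=False))
```

prints

```
 class  area_km2  proportion_pct
  BL&W    333.88           28.40
 L-FVC    105.28            8.95
SL-FVC    107.60            9.15
 M-FVC    311.72           26.51
 H-FVC    317.20           26.98
station validation: MAE=1.72 K  RMSE=2.29 K  n=15
URI=0.5810
    zone  slope    r2     n
offshore -2.989 0.776  8386
  middle -4.476 0.870 12337
  inland -6.020 0.937  8669
```

Reading the numbers: about 27% of the land is high vegetation cover; the
retrieval error against the 15 noisy stations matches the injected 2 K
station noise; the URI of 0.58 sits a little above the 0.6-neutral midpoint
range; and the LST–FVC cooling slope steepens from −3.0 K/FVC offshore to
−6.0 K/FVC inland — the scene was constructed with slopes (−3, −4.5, −6),
and the fits recover them.

The same stages are available from the shell: `coastveg run --config
config.yaml`, plus the per-stage subcommands `synth-scene`, `fvc`, `lst`,
`uhi`, `zones` and `report` (see `coastveg --help`).

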