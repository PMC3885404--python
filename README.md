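# rockveg

Voxel-based mapping of vegetation structure on and around granite
outcrops from discrete-return airborne LiDAR, with regression links to
rainfall and soil depth and a rainfall-reduction projection that flags
putative climate-change refugia.

Granite outcrops (inselbergs) shed water, nutrients and sediment to
their fringes, so the water-gaining "on-flow" zones at their base carry
taller and denser vegetation than the surrounding landscape and are
candidate refugia as regional rainfall declines. `rockveg` implements
the full analysis chain for this setting, for ecologists and remote-
sensing practitioners working with low-density (< 1 point/m²) discrete-
return LiDAR:

1. **Ingest** — read point clouds (CSV schema with return number,
   intensity, scan angle, flight-run id, ground flag), resolve
   overlapping flight runs per 4 m cell by smallest mean scan angle,
   triangulate ground returns into a 2 m DEM (TIN), and normalize
   return heights above ground.
2. **Vertical profiles** — record vegetation presence/absence in voxels
   (4 × 4 × 1 m), compute the percentage of filled voxels (PVF) per 1 m
   height bin in a 3 × 3-cell window, smooth vertically with a
   (0.27, 0.46, 0.27) kernel, detect canopy layers with a 20 % PVF
   threshold, and sample each profile at 18 height intervals over
   1–80 m.
3. **Structural classes** — standardize profile features, reduce with
   PCA (99 % variance), cluster with a migrating-means (ISO) procedure
   that dissolves classes under 1 % of the area, merge class libraries
   across areas, and classify scenes with a minimum-distance
   (nearest-centroid) classifier; agreement with field labels is scored
   with Cohen's κ.
4. **Polygons** — segment the canopy-height model into height-
   homogeneous polygons (deterministic region merging), label each with
   its dominant class, and optionally resolve moss-mats from bare rock
   by relative RGB brightness.
5. **Habitat models** — per-plot soil-depth probability
   (pDS = fraction of five probes deeper than 0.5 m), structure
   statistics over a 4 m plot buffer, and multivariate linear models of
   canopy height / ground cover on rainfall (R), elevation range (EV)
   and pDS with backward elimination (α = 0.05) and leave-one-out Q²
   (statsmodels-style `Model.fit() → Results.summary()`).
6. **Projection** — the fitted region-wide forms, with x = pDS·R,

       CH(x) = 0.21 + 28.4·10⁻⁴ x + 2.9·10⁻⁵ x²       (m)
       GC(x) = 25.5 + 69.6·10⁻³ x                      (%)
       pDS   = 0.55 + (10.89·CH + 8.93·GC − 0.73·R)/1000

   predict each polygon's structure under a rainfall multiplier
   (default 0.8, a 20 % reduction), and polygons are reclassified to
   the nearest structural class restricted to classes with equal or
   lower mean canopy height *and* ground cover.

A first-class synthetic-scene generator (`rockveg.synth`) builds
virtual outcrop scenes — dome DEM, soil-depth and pDS fields with
on-flow channels, canopy truth drawn from the equations above, and a
simulated two-run discrete-return point cloud at 0.63 pulses/m² — so
every stage is testable without survey data.

## Worked example

```python
from rockveg import predict_canopy_height, predict_ground_cover, estimate_pds

for pds, r in [(0.5, 500), (0.5, 400), (0.7, 400)]:
    print(f"pDS={pds:.1f} R={r}: CH = {predict_canopy_height(pds, r):.2f} m, "
          f"GC = {predict_ground_cover(pds, r):.1f} %")
print(f"pDS(CH=31.10, GC=87.75, R=1044) = {estimate_pds(31.10, 87.75, 1044):.4f}")
```

prints

```
pDS=0.5 R=500: CH = 2.73 m, GC = 42.9 %
pDS=0.5 R=400: CH = 1.94 m, GC = 39.4 %
pDS=0.7 R=400: CH = 3.28 m, GC = 45.0 %
pDS(CH=31.10, GC=87.75, R=1044) = 0.9102
```

Reading: at a site with 500 mm annual rainfall and an even chance of
soil deeper than half a metre, a 100 mm rainfall reduction costs about
1 m of canopy height (2.73 → 1.94 m) — and moving to deeper soil
(pDS 0.7) more than compensates (3.28 m). The last line inverts the
relationship: tall (31 m), dense (88 %) forest at 1044 mm rainfall
implies deep soil with probability 0.91.

The full pipeline runs from the command line on a synthetic scene:

```sh
rockveg run --seed 42 --out scene_out/
```

producing the DEM and canopy-height rasters (`.asc`), per-cell profile
features, the class library (JSON), classified polygons (GeoJSON), the
fitted plot models, and the per-class area-change summary under the
rainfall scenario.

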