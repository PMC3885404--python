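# Methods

This note records the models and procedures implemented in `rockveg`,
the defaults and why they were chosen, and what the synthetic scenes do
and do not establish about real survey data.

## Point-cloud preparation

Overlapping flight runs double point density along swath edges, which
would bias any presence/absence statistic. Returns are gridded at 4 m
and, in every cell containing more than one run, only the run with the
smallest mean absolute scan angle is kept (the run scanned closest to
nadir penetrates canopy best). Ties are broken by the lexicographically
smaller run id — an arbitrary but deterministic rule. Deduplication
never increases the point count and is idempotent.

The bare-earth model is a linear interpolation on the Delaunay
triangulation (TIN) of all ground-flagged returns, sampled at 2 m cell
centres; it reproduces affine surfaces to machine precision. Cell
centres outside the convex hull are filled with the nearest ground
point's elevation and flagged as extrapolated. Ground classification is
taken from the input flag — the clouds this pipeline targets arrive
pre-classified; a lowest-return-per-cell fallback exists but is off by
default because it misclassifies dense low shrub. Normalized heights
below zero (TIN undershoot) are clamped to 0 and counted; grids are
snapped to floor multiples of the cell size with half-open cells, so
cell membership is unambiguous.

## Vertical PVF profiles

Vegetation presence is recorded per voxel (processing-grid footprint ×
1 m height bin, ceiling 80 m) rather than as return fractions, because
presence/absence is robust to the residual point-density variation a
low-density survey always carries. The percent of filled voxels (PVF)
at each bin is computed over a 3 × 3-cell window (12 × 12 m at the 4 m
default); edge cells use their truncated sub-window with its own
denominator, so PVF stays a percentage everywhere. The window size is
configurable; the voxel footprint equals the processing cell.

Profiles are smoothed vertically with the three-tap kernel
(0.27, 0.46, 0.27) (weights renormalized at the profile ends), which
suppresses single-bin dropouts without displacing layer edges by more
than a bin. Canopy layers are maximal runs of bins with PVF ≥ 20 % —
two of the nine window voxels. The threshold is applied to the smoothed
profile by default (a raw-profile mode is available); layers are
enumerated top-down so that layer 1 is the uppermost and its top edge
defines the cell's canopy height, and the uppermost layer's thickness
is the crown thickness. For classification, each profile is sampled at
18 contiguous height intervals covering 1–80 m whose widths grow from
1 m near the ground (where structure is richest) to 20 m at the top;
the default edge table is
1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 15, 18, 22, 26, 30, 36, 45, 60, 80
and is configurable and recorded in output metadata. Cell-level ground
cover is the percentage of first/single returns intercepted by
vegetation; band cover splits above-ground returns into < 1 m, 1–3 m,
3–10 m and > 10 m bands (lower-closed intervals).

## Structural classification

Features (18 sampled PVF values, canopy height, cover, crown
thickness; intensity optional and off by default because across-flight
intensity is not radiometrically corrected) are z-scored, then reduced
to the smallest set of principal components explaining 99 % of the
variance. Clustering is a migrating-means (ISO) procedure: k-means++
seeded Lloyd iterations to a 10⁻⁴ centroid-shift tolerance, followed by
dissolution of clusters holding under 1 % of the samples (smallest
first, members reassigned to the nearest surviving centroid). Optional
ISODATA-style split/merge steps exist behind flags but default off —
they add tuning burden without changing the tested behaviour.
Class counts are data-dependent outcomes, not targets.

Libraries from separate training areas are combined by single-link
merging of centroids within 0.5 standardized units; merged centroids
and class means are member-weighted, and min/max envelopes are taken
for the per-layer statistics (the merged "median" is a weighted mean
of medians — exact order statistics would need the raw members).
Mapping profile classes to broader named structural classes is analyst
input, supplied as a two-column CSV.

Scenes are classified per cell by minimum Euclidean distance to class
centroids in the library's standardized space; ties go to the smallest
class id and non-finite features get an unclassified sentinel. Cohen's
κ is computed from the confusion matrix in the standard form
(p_o − p_e)/(1 − p_e) and is undefined (raised) for degenerate margins.

## Segmentation and polygons

The canopy-height model is partitioned by deterministic cheapest-first
region merging: all cells start as regions, and the adjacent pair whose
union spans the smallest height range merges first, stopping when the
cheapest union would exceed the scale parameter (metres of height
range). Executed merge costs are nondecreasing, so the merge sequence
at a small scale is a prefix of the sequence at a larger one — polygon
count is provably non-increasing in scale, and every region's internal
height range is bounded by the scale. Two scales are used: "local"
(default 2 m range, single crowns) and "vegetation" (default 5 m,
stands); these defaults are exposed in config and are this package's
choices. Polygon geometry follows cell boundaries without smoothing.

Each vegetation-scale polygon takes the class covering the largest
share of its cells (ties to the smallest id). Polygons with no
above-ground returns are bare; where a brightness raster (sum of the
three RGB digital numbers) and per-site thresholds are configured, a
bare local-scale patch whose mean brightness *relative to its enclosing
vegetation-scale polygon* falls between the thresholds is flagged as a
moss-mat. Relative rather than absolute brightness is used because
illumination varies strongly across an outcrop; with no thresholds the
step is skipped and bare areas stay bare rock (the realistic outcome
for dry-season imagery of arid sites).

## Habitat models

pDS is the fraction of the five probe depths strictly greater than
0.5 m, hence quantized to {0, 0.2, …, 1}. Plot structure statistics are
taken over classified polygons intersecting the plot footprint (1, 5 or
20 m square by habitat type) dilated by 4 m — the dilation absorbs
hand-held GPS error. Area-weighted mean cover and maximum canopy height
use all intersecting polygons; class-weighted statistics use library
class means and only polygons covering at least a quarter of the
buffered plot, so a sliver cannot inject a foreign class mean.

Structure–environment models are ordinary least squares on rainfall
(R, mm yr⁻¹), site elevation range (EV, m — the spread between the
highest and lowest plot elevations, attached to every plot of a site)
and pDS, with the three pairwise interactions as candidates. Backward
elimination removes the least significant term (largest p ≥ 0.05), one
per refit, with no main-effect hierarchy — interactions may survive
without their mains. Aliased terms are detected by rank deficiency and
dropped first. Fit robustness is reported as leave-one-out
Q² = 1 − PRESS/TSS, computed with the hat-matrix identity for the LOO
residual (e_i/(1 − h_ii)), which equals explicit refitting exactly;
Q² ≤ R² for any OLS fit.

The region-wide closed forms (see README) are fixed-coefficient
predictors in x = pDS·R. Physical clamps — CH ≥ 0, GC ∈ [0, 100],
pDS ∈ [0, 1] — are applied to their outputs.

## Scenario projection

Projection substitutes space for time: relationships fitted along the
rainfall gradient are applied to a rainfall-reduced future (default
multiplier 0.8). Each polygon's pDS is estimated from its present mean
height, cover and rainfall if not measured. Two modes exist. *Delta*
(default) adds the equation-predicted change
CH(pDS, m·R) − CH(pDS, R) to the present values; *absolute* replaces
them with raw equation outputs. Delta is the default because it is
exact at multiplier 1 and immune to the equations' bias at any single
site.

Reclassification selects the structural class with the nearest mean
(CH, GC) — Euclidean in the two axes standardized by their across-class
spreads — restricted to classes whose mean canopy height and ground
cover are both ≤ the current class's means; the current class always
qualifies, so the choice is total. In delta mode the search point is
anchored at the *current class mean* plus the predicted change rather
than at the polygon's own values: classes are internally heterogeneous,
and anchoring at a polygon's off-mean values would reshuffle classes
even under a no-change scenario. This guarantees that a multiplier of
1.0 changes no class, and that every reassignment moves weakly downward
in both class-mean axes. Area proportions per class are reported for
the whole scene or any polygon subset, and sum to 1 in both epochs.

## Synthetic scenes

The generator emulates the landform the pipeline targets: a spherical-
cap granite dome (default 120 m radius, 40 m tall) on a gently sloping
plain, mean soil depth thin on rock (0.05 m) and deepening off the rock
edge with a 30 m e-folding length toward 0.7 m, plus radial on-flow
channels with an extra 0.6 m of soil. Probe-scale soil depth is
Normal(d, 0.15 m), giving pDS in closed form. Truth canopy height and
ground cover follow the fitted equations at the site rainfall (default
512 mm, a mid-gradient value) plus Gaussian noise (σ = 0.35 m and 6 %),
so fringe-versus-rock contrast holds by construction. The point cloud
simulates two overlapping flight runs at 0.63 pulses/m² with linear
scan-angle profiles, up to four returns per pulse spread through the
crown depth, and single ground returns over bare rock. Survey plots
(OF on the rock top, INT at the edge, ON on the fringe, with 1/5/20 m
footprints) carry five probe draws each, so empirical pDS is an
unbiased five-probe estimate of the field.

For regression studies, `gen_regression_plots` spreads plots over the
16 surveyed sites' rainfall values (314–1208 mm), quantizes pDS to
five-probe fractions, and calibrates the noise σ so the x-signal
explains ≈ 0.9 of the variance.

What the synthetic scenes do *not* emulate: occlusion (returns are
drawn from the truth canopy without shadowing), species composition,
off-terrain objects, GPS error in plot coordinates, and radiometric
intensity structure (intensity is band-dependent noise). Passing tests
therefore demonstrate the correctness and internal consistency of the
algorithms under the stated statistical structure, not sensor-level
fidelity.

## Problem sizes and numerical choices

The default synthetic scene is 500 × 500 m (~190 k pulses, ~300 k
returns, ~15 k profile cells); the full pipeline completes in well
under a minute on one CPU, and the test suite uses a 200 m scene for
pipeline-level checks. Tolerances: centroid-shift 10⁻⁴ for clustering,
10⁻¹⁰ for the hat-matrix/refit Q² agreement, machine precision for TIN
planarity. Tie-breaks are everywhere deterministic (smallest id or
lexicographic). Degenerate inputs — all-identical samples, empty
classes, profiles with no vegetation, plots intersecting nothing — are
handled with warnings and sentinels rather than failures, as documented
per function.

## Known limitations

The canopy-height quadratic's small intercept (0.21 m) is not
recoverable to tight relative precision from noisy plot-scale fits —
its standard error under any realistic design exceeds the coefficient's
own magnitude at achievable signal-to-noise, and collinearity between x
and x² can eliminate the linear term entirely under backward
elimination; the curvature term and the ground-cover model recover
well. Fire regimes, water-table dynamics and within-class floristic
turnover are outside the model, and the space-for-time assumption —
that spatial structure–climate gradients predict in-situ temporal
change — is inherited, not tested.
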