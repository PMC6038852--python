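# Methods

This note documents the algorithms, conventions and parameter choices of
`firepatches`, including the places where the published description of
this class of pipeline is ambiguous and a concrete convention had to be
chosen.

## Patch reconstruction

**Definition.** A fire patch is a connected component of the graph whose
vertices are burned pixels (burn date > 0) and whose edges join
queen-adjacent (8-neighbour) pixels with |Δ burn date| ≤ Δt_co, the
temporal cut-off in days. This pairwise rule is taken as normative; the
historical description of the algorithm as a date-windowed sweep with
clump merging is, read literally (strict inequalities on the window),
vacuous, and up to endpoint convention equivalent to single-linkage
clustering under the pairwise rule. Consequences worth knowing:

* Membership is transitive: a chain of pixels dated 1, 4, 7, 10 with
  cut-off 3 forms one patch although its ends differ by 9 days.
* Increasing the cut-off can only merge patches, never split them: the
  partition at cut-off c refines the partition at any c′ > c. This is
  tested exactly.
* No-data pixels (negative codes) act as unburned: they break
  connectivity.

The production implementation builds the edge list vectorially and labels
components with `scipy.sparse.csgraph.connected_components`; an
independent pure-Python breadth-first search (`brute_force_patches`) is
kept as an oracle, and the two are asserted identical on hundreds of
randomized rasters.

**Determinism.** Patches are ordered by their first pixel in row-major
order; ids embed survey, cut-off, tile and serial, so identical inputs
give byte-identical catalogues.

**Months and years.** Patches are built on the full date axis first and
then annotated with the calendar month/year of their mean burn date; a
patch straddling a month boundary is never truncated. Whether the
historical monthly processing truncated such patches is undocumented;
no-truncation is this package's choice.

**Filtering.** Traits are computed for patches with ≥ 5 pixels
(`min_pixels`, default 5). An optional area floor (`min_area_ha`, e.g.
107 ha ≈ a 5-pixel fire at 463 m resolution on the equator) equalizes the
size class across products of different resolution.

## Traits

* **Perimeter** counts unit cell edges adjacent to exactly one patch
  pixel, so interior hole boundaries contribute (hole handling is a
  documented choice; the alternative, outer-boundary-only, is not
  offered).
* **Core pixels** have all 8 neighbours inside the patch (4-neighbour
  variant behind a flag). The neighbourhood is evaluated on the patch's
  own footprint, not the global burned mask: a pixel touching a
  *different* patch's pixels is not core.
* **Areas** are geodesic on a spherical Earth (R = 6371 km): each pixel
  contributes R²·Δλ·(sin φ_N − sin φ_S) for its own cell, i.e. ~cos(lat)
  scaling. A 463 m pixel on the equator is ≈ 21.44 ha.
* **Shape index.** Default is the compact-patch normalization
  SI = P/p_min(N) with p_min = 4n, 4n+2 or 4n+4 (n = ⌊√N⌋) — the
  landscape-ecology convention, which reproduces published catalogue
  values. The literal formula 0.25·P/√N is available as
  `variant="sqrt_formula"`; the two agree only when N is a perfect
  square.
* **Fractal correlation dimension** D₂ = 2·ln(P/4)/ln(N) lies in [1, 2]
  for connected patches (P ranges from p_min ≈ 4√N to ≤ 4N); singletons
  get NaN.
* **Burn dates.** BD_mean is the arithmetic mean of pixel dates, reported
  to 2 decimal days; date-uncertainty layers of the input products are
  ignored (the algorithm uses dates only).

## Standard deviation ellipse

Centre = coordinate mean. The 2×2 covariance of the centred coordinates
is computed with an (n − 2) denominator and the half-axes are √2 times
the eigen-standard-deviations — the documented convention of the
classical centrographic implementation; variants differing by the √2 and
n vs n−2 factors exist, and the published worked example cannot arbitrate
between them because the underlying pixel coordinates are unpublished.
For Gaussian-blob patches this scaling covers ≈ 63–66% of the pixels
(checked statistically in the tests, not hard-asserted per patch).

θ is the azimuth of the major eigenvector, clockwise from north, folded
to [0, 180) since an ellipse axis has no sign. The fit is repeated in a
per-patch equirectangular projection x = Δlon·111.320·cos(lat₀),
y = Δlat·110.574 (km); R_SDE and E_SDE are defined from the km half-axes
and satisfy R² + E² = 1 exactly. Note the projection is slightly
anisotropic (111.320 vs 110.574 km/°), so exact symmetry/rotation
properties hold in km space, not in raw degrees. Fewer than 3 points give
a NaN fit; collinear points give σ_X = 0, R = 0 and a degeneracy flag.

## Size-distribution fit

The model is N_f = α·A_f^(−β). Per catalogue (or per 1° cell):

1. **Profile histogram**: geometric bin edges spanning [min, max] of the
   areas, 5 bins per decade by default; each bin carries count n_i,
   density n_i/width and Poisson error √n_i.
2. **χ² fit in count space**: the model count in bin i is α·∫A^(−β)dA
   over the bin (exact within-bin integration), and
   χ² = Σ (n_i − m_i)²/n_i over occupied bins. Empty bins are excluded
   (1/n weight undefined); ≥ 3 occupied bins are required. α is linear
   and profiled out analytically; β is minimized by bounded 1-D search
   seeded from a weighted log-log regression.
3. **σ_β** is the mean half-width of the χ²(β) profile at Δχ² = 1, with α
   re-minimized at every β.

Validation: on truncated-Pareto samples (inverse-CDF, the sampler is
itself KS-tested against the closed-form CDF) with β ∈ {1.5, 2.0, 2.5}
and n = 10 000, the mean bias is < 0.01 and ±2σ_β covers the truth in
every one of 20 seeds per β. Poisson bin errors are known to
underestimate uncertainties on real, imperfectly power-law data.

**Gridding.** Patches are assigned to half-open 1° cells by their centre;
cells report fire count, mean/std of PAR, SI, D₂, R_SDE and E_SDE, and
(β, σ_β) when the cell holds at least `min_fires_for_fit` (default 20)
patches. Grid comparison reports β_A − β_B and the agreement level
|β_A − β_B|/√(σ_A² + σ_B²) per cell.

## Tiling

For parallel processing, the domain is covered by 3.5° tiles whose 2.5°
cores partition it and whose 0.5° borders overlap the neighbours. Cores
are half-open, so a patch centre on a shared core edge belongs to exactly
one tile; each patch is kept by the tile whose core contains its centre.
The tiled path reproduces the whole-raster catalogue exactly for fires
smaller than the border (property-tested); larger fires can still be
truncated at tile edges — an inherent limitation of the scheme, which is
why the whole-raster path is the reference.

## Synthetic data

The generator emulates burn-date tiles at MODIS-like (463 m) or
MERIS-like (300 m) nominal resolution. Each event grows daily from an
ignition pixel as an ellipse (minor radius = spread_rate·day, major =
elongation × minor, oriented by an azimuth); a pixel burns on the first
integer day the front covers its centre, so dates increase outward within
[start, start + duration]. Overlapping events resolve first-burn-wins —
each pixel keeps its earliest date, as monthly burned-area products keep
one date per pixel. Everything is deterministic given the event list; the
spec's seed drives the randomized event factories.

`fragmented_fire_spec` draws complete-fire areas from a truncated power
law (β = 1.2 over 10–2500 px), splits each fire into up to 7 Dirichlet
stick-breaking pieces (larger fires fragment more) burning 4–12 days
apart at adjacent locations, on a 900² grid with 650 fires. Small
cut-offs reconstruct the pieces; large cut-offs reassemble whole fires.
This reproduces the expected ecology-scale behaviour: the fitted β
decreases from the 3-day to the 14-day cut-off on every such raster, and
the cutoff-wise mean β over an ensemble of rasters is monotonically
non-increasing. Strict per-raster monotonicity at *every* intermediate
step is not asserted: the χ² fit has ±few-percent wobble on distributions
that are only approximately power-law, so the monotone trend is an
ensemble property, which is how it is observed in practice (regional
medians), and that is what the tests check.

What the generator does **not** emulate: physical spread dynamics (fuel,
wind fields, Rothermel behaviour), detection gaps and date uncertainty,
cloud-driven missing data, or re-burning within one event. Passing tests
therefore demonstrate the correctness of the reconstruction and
measurement machinery under controlled geometry, not the fidelity of any
particular satellite product.

## Numerical and interface choices

* Unburned = 0, unmapped/no-data < 0; burn dates are integer days.
* Pixel (row, col) are 0-based, row 0 northernmost; patch centres use
  pixel-centre coordinates in degrees.
* GeoTIFF georeferencing via ModelPixelScale/ModelTiepoint/GeoKey tags;
  only geographic (lat/lon) CRSs are accepted — projected inputs must be
  reprojected upstream. NetCDF output is classic NetCDF3 via the scipy
  backend for maximum portability.
* Catalogue CSVs have one row per patch per cut-off, columns in the
  canonical trait order; patch ids embed the cut-off so files are
  self-describing.
* Problem sizes in the test-suite: oracle equivalence on 200 randomized
  rasters up to 60², β recovery at n = 10 000 × 20 seeds × 3 exponents,
  cut-off/β trend on four 900² rasters (~650 fires each), tiling
  invariance on a 5°×5° domain (2×2 tiles of 3.5°). These sizes give
  stable statistics while keeping the whole suite around a minute of
  compute.

## Known limitations

* The flood fill treats burn dates as exact; products' date-confidence
  layers are ignored.
* Patches wider than the 0.5° tile border can be split by the tiled path.
* σ_β from Poisson-weighted χ² under-covers on non-ideal data.
* The compact-normalization SI and the hole-inclusive perimeter are
  conventions; alternative published formulas give slightly different
  values (both SI variants are exposed).
* Cross-year patch stitching beyond the loaded date axis is out of scope.
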