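# firepatches

Reconstruct individual fire patches from pixel-level burned-area rasters
and measure their morphological functional traits.

Satellite burned-area products (e.g. the 463 m MODIS MCD64A1 or the 300 m
MERIS fire_cci grids) record, for each burned pixel, the day it burned —
but not which fire it belonged to. `firepatches` turns such burn-date
rasters into a catalogue of fire events and gridded summaries for fire
ecologists, emission modellers and anyone benchmarking the fire modules of
vegetation models:

1. **Patch reconstruction.** Burned pixels are aggregated into patches by a
   temporally constrained flood fill: two queen-adjacent (8-neighbour)
   pixels belong to the same patch when their burn dates differ by at most
   a cut-off Δt_co (days). Patch membership is the transitive closure of
   this rule — single-linkage clustering on the pixel adjacency graph.
   Cut-offs of 3, 5, 9 and 14 days are the conventional choices.
2. **Functional traits.** For every patch with ≥ 5 pixels: pixel and core
   counts (a core pixel is surrounded on all 8 sides by the patch),
   geodesic areas A and A_core (ha), perimeter P (pixel sides), the
   perimeter-to-area ratio P.A.R. = P/N, shape index
   S.I. = P/p_min(N) (1 = maximally compact), fractal correlation
   dimension D₂ = 2·ln(P/4)/ln(N), core-area index C.A. = A_core/A, burn
   dates, and the standard deviation ellipse (SDE): half-axes σ_X ≤ σ_Y
   and azimuth θ in degrees and in a local flat projection (km), with
   ellipse ratio R_SDE = σ_X,km/σ_Y,km and eccentricity
   E_SDE = √(1 − (σ_min/σ_max)²).
3. **Level-2 grids.** 1°×1° maps of fire counts, trait means/standard
   deviations, and the fire-size power law N_f = α·A_f^(−β) fitted per
   cell by χ² minimization over logarithmic size bins with Poisson
   (√count) errors; σ_β is read from the χ² profile at Δχ² = 1. Two grids
   (e.g. two surveys) can be compared cell-by-cell in units of the pooled
   σ_β.

A synthetic-fire module generates burn-date rasters with known ground
truth (elliptical daily spread, first-burn-wins overlap, optional
fragmentation of fires into temporally offset pieces), so the whole
pipeline is testable without satellite downloads.

## Worked example

`examples/01_simulate_and_build_patches.py` simulates two fires igniting
2 days apart on adjacent ground and reconstructs patches:

```
raster: 58 burned pixels, 2 ground-truth events
cut-off  1 d -> 2 patch(es), sizes [29, 29]
cut-off  5 d -> 1 patch(es), sizes [58]
```

With a 1-day cut-off the two events stay separate; at 5 days the 2-day
date difference where their fronts touch is within tolerance and they
merge into one patch — the cut-off is exactly the lever that decides what
counts as "one fire".

`examples/03_size_distribution_fit.py` validates the power-law fitter on
10 000 sizes drawn with a known exponent:

```
true beta      : 2.0
fitted beta    : 2.009 +/- 0.011
chi2 (min)     : 4.0 over 15 bins
```

The other examples compute the full trait record of an elongated fire
(recovering its imposed spread azimuth from the SDE), build 1° trait/β
grids and compare them at the σ level, and recompute a published
four-patch worked example (`examples/05_worked_example.py`), reporting
which printed cells reproduce and which are known rounding/typo
discrepancies.

There is also a thin CLI:

```bash
firepatches simulate --seed 3 --out burn.tif
firepatches traits burn.tif --cutoff 5 --out patches.csv
firepatches grid patches.csv --out traits.nc
firepatches demo-worked-example
```

A full run over one or more rasters (`firepatches run config.yaml`)
writes, per cut-off N, the patch catalogue
`fire_patches_<SURVEY>_final_co_<N>.csv` and the gridded product
`trait_map_<SURVEY>_1.0deg_co_<N>.nc`.

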