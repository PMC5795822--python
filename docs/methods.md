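# Methods

`vinesense` implements a per-plant surveillance pipeline for row crops
surveyed by UAV: hyperspectral/multispectral imagery plus a photogrammetric
point cloud are reduced, plant by plant, to vegetation indices, canopy
height, and spectral signatures, then joined with ground observations
(expert vigour scores, soil conductivity) and analysed by Pearson
correlation. The motivating system is grape phylloxera in vineyards: a
root-feeding insect whose above-ground symptoms are reduced canopy vigour
and altered leaf reflectance (brighter visible region, shallower
chlorophyll-absorption well near 670 nm, depressed NIR plateau).

## Reflectance calibration

Scene radiance is converted to reflectance by band-wise division by the mean
radiance of a white reference board imaged before/after flight. Boards are
screened for sensor saturation first: a band whose fraction of pixels at the
sensor ceiling exceeds a threshold (default 1%) invalidates the reference,
since division by a clipped mean biases every pixel. The usable patch is
either supplied as a window or auto-selected as the fixed-size window of
maximal mean radiance (exhaustive summed-area scan). Reflectance is not
clipped at 1.0 — specular or brighter-than-board pixels are physical — but
values above 1.2 are counted in the QC log. Calibration is linear by
construction (`calibrate(a·L) = a·calibrate(L)`), and exactly inverts the
synthetic illumination model in the noiseless case.

## Vegetation indices

Twenty-one indices are registered: NDVI, green NDVI, NDRE, MCARI, MCARI1,
MCARI2, TCARI, OSAVI, and the blue/green and blue/red pigment ratios, in
hyperspectral (`_H`) and/or 5-band multispectral (`_M`) variants, plus the
six phylloxera indices PI1–PI6 (normalised differences of band pairs
selected from infested-vs-healthy difference spectra). Hyperspectral band
symbols (R504, R670, …) resolve by nearest wavelength on the cube's grid
(tolerance 3 nm; ties to the lower wavelength); no spectral averaging window
is applied, since the formulas are single-wavelength. Multispectral sources
expose only the five fixed camera centres (475/560/668/717/840 nm);
requesting a narrow-band index from them is a capability error, not a
silent approximation. TCARI is evaluated exactly as printed, with the
R700/R670 factor inside the bracket; MCARI2 uses the original
Haboudane-2004 denominator `sqrt((2·NIR+1)² − (6·NIR − 5·sqrt(Red))) − 0.5`.
Zero denominators yield nodata with a logged count rather than aborting the
raster. Normalised-difference forms are bounded in [−1, 1] and invariant to
uniform reflectance scaling; OSAVI/MCARI/TCARI carry additive constants and
are neither.

## Digital vigour model

On sloping terrain, elevation can vary more within one row than the height
of the vines, so canopy height is measured against a reconstructed bare
earth, not a flat datum.

1. **Ground filtering.** The dense cloud is seeded with per-cell minima on a
   coarse grid (default 1 m), the seeds triangulated into a provisional
   surface, and points admitted iteratively: a candidate joins the ground
   when its supporting facet (the containing TIN triangle, or the plane of
   its three nearest ground points outside the hull) has slope at most
   `max_angle` (default 70°, the maximum admissible ground slope) and the
   candidate lies within `max_distance` (default 0.6 m) vertically of that
   plane. Collinear support degrades to a distance/inclination test on the
   segment to the nearest ground point. Iteration runs to a fixpoint; prior
   labels are ignored, so the filter is idempotent. The slope bound on the
   supporting facet, rather than on segments to individual vertices, is what
   prevents acceptance from "creeping" up a steep planar face or a canopy
   flank band by band.
2. **Rasterisation.** DSM = per-cell maximum z over all points (canopy
   tops); DTM = per-cell mean z of ground points, with cells under the
   canopy filled by linear interpolation on the triangulation of populated
   cell centres (IDW over the 8 nearest populated cells outside the hull).
   Default cell 0.05 m, chosen as a quarter of the 0.2 m zonal radius.
3. **DVM.** DVM = DSM − DTM; interpolation can leave small negatives, which
   are counted below −0.05 m and clipped to zero; DSM-nodata stays nodata.
4. **Zonal statistics.** Per plant, max/mean/count over DVM cells whose
   centres lie within 0.2 m of the trunk (cell-centre membership makes the
   counts reproducible). Max is the vigour statistic; mean is also reported.
5. **Classes.** Heights map to vigour classes against the trellis wires:
   class 5 at or above the top wire (1.75 m), 4 from the middle wire
   (1.55 m), 3 from the bottom wire (1.2 m), 2 above `dead_height`
   (0.1 m), 1 otherwise — and also 1 when no DVM cell is in reach (a dead
   plant leaves no canopy returns). Treating "at the top wire" as class 5
   is a convention; the field description of the 4/5 boundary is
   qualitative. IDW interpolation (power 2) turns per-plant classes into
   continuous vigour maps.

## Spectral signatures and index proposal

Per-plant signatures are means/SDs over cube pixels whose centres fall in a
0.3 m disc around the trunk (an automated stand-in for hand-drawn GIS
polygons; arbitrary shapely polygons are also accepted). The disc membership
test carries a 1e-9 relative tolerance so rim-aligned cell centres are
included deterministically. Class signatures pool all member plants' pixels,
hence equal the pixel-count-weighted mean of the member signatures exactly.
The infested-minus-healthy difference spectrum (SDs combined in quadrature)
is smoothed by a 5-band moving average — raw ~2.2 nm sampling is noisy —
and its |difference| local maxima and zero crossings are ranked; the top 7
are reported as bands of interest. Every pair of selected bands yields a
proposed normalised-difference index (R_hi − R_lo)/(R_hi + R_lo), the
construction behind the PI family; the 504/522 nm pair reproduces PI1.

## Data integration and correlation

The attribute table has one row per vine: identity and location,
block/row/panel, variety, expert vigour (panel scores broadcast to member
plants; unscored panels give missing values), DVM max/mean, one column per
index (mean over the plant's canopy disc), and EM38 soil conductivity.
Pearson correlations use pairwise complete cases — expert scores are
panel-sparse, so listwise deletion would discard most plants — with at
least 3 complete pairs required and zero-variance pairs reported missing
with a warning. Expert classes are treated as numeric 1–5. The report ranks
variables by r against reference columns (expert vigour and DVM max) and
flags |r| > 0.4 as "strong"; this mirrors a reporting convention, not a
significance test, and no multiple-testing correction is applied because
none is part of the procedure being implemented.

## Synthetic vineyard generator

No field data ship with the package; all tests run against a generator with
exact ground truth. What it emulates, and the defaults:

- **Geometry:** 6 rows × 30 vines, 3.0 m row spacing, 1.5 m vine spacing,
  panels of 5 vines (expert-score granularity), 2 m margins.
- **Terrain:** smooth surface (planar hillside trend carrying 80% of the
  relief plus low-frequency sinusoidal undulation carrying 20%), rescaled
  so max − min equals `terrain_relief` exactly (default 5 m, scenario range
  0–24 m). Keeping the undulation share small keeps local slopes realistic
  (tens of degrees at most) even when 24 m of relief is compressed into a
  ~50 m test block; real sites spread such relief over hundreds of metres.
- **Infestation:** seeded-focus contagion on the row lattice — 2 foci,
  along-row spread probability 0.5 per neighbour per round, between-row
  0.1, rounds until the target rate (default 15%) is reached. This is the
  minimal two-parameter mechanism reproducing the field observation that
  infestation extends along rows; the rates themselves are placeholders, as
  no quantitative spread rates are published.
- **Vigour/heights:** healthy vines draw classes 4–5 (0.35/0.65), infested
  2–3 (0.5/0.5); the true height is the class anchor (0.9/1.4/1.65/1.9 m)
  ± 0.06 m uniform jitter, which stays inside the class's wire band, so the
  generated class always equals the wire rule applied to the height.
- **Point cloud:** ground points at 60 m⁻² on the terrain ± 0.02 m noise,
  omitted under living canopies (occlusion); per vine, 250 m⁻² canopy
  points over a 1.2 × 0.6 m footprint, 40% on the crown top at the true
  height ± noise and the rest between 75% of the height and the top — image
  matching reconstructs the visible crown, not the shaded interior or the
  trunk.
- **Reflectance:** 274 bands over 400–1000 nm (~2.2 nm sampling). Canopy
  pixels take the plant's endmember + N(0, 0.01) noise; inter-row pixels a
  soil spectrum rising monotonically across the VNIR. Endmembers are smooth
  analytic curves (green peak ~550 nm, chlorophyll well ~670 nm, red edge
  690–740 nm, NIR plateau) with the infested/healthy orderings above; no
  published signature values exist, so the magnitudes are free parameters.
- **Radiance:** reflectance × a smooth positive illumination spectrum, with
  an 8×8 white patch equal to the illumination (± optional noise), making
  calibration an exact inverse in the noiseless case.
- **Expert scores:** per panel, the modal true class of its plants (ties to
  the lower class), perturbed ±1 with probability `error_rate` (default
  0.1); at the class extremes the perturbation points inward so a perturbed
  panel never keeps its modal class.
- **EM38:** i.i.d. N(50, 10²) mS/m, independent of every truth field — the
  testable null behind "soil conductivity correlates with nothing".

All generators are deterministic in a single seed via tagged sub-streams.
`expected_vigour_height_correlation` replays only the class/height/expert
sampling chain over many replicates to give the expectation and
across-seed SD of Pearson(expert, height) — the yardstick against which
the full pipeline's measured correlation is judged.

**What passing does not show.** The generator has no BRDF, shadows,
radiative transfer, within-canopy spectral gradients, georeferencing error,
or temporal growth; its noise is i.i.d. Gaussian. Recovery results
(height RMSE ~0.04 m, ≥95% class agreement) therefore demonstrate the
correctness of the algorithms under the stated model, not field accuracy.
Field correlations between expert vigour and the DVM were reported around
0.4–0.5 on proprietary imagery that is not deposited; the synthetic
scenario reproduces the *structure* of that analysis (positive
vigour–height coupling, EM38 null), not those numbers.

## Numerical choices and degenerate inputs

- Raster convention: planar metric CRS, origin at the upper-left cell
  corner, row-major, north-up, half-open cell intervals; geotransforms
  survive IO round trips exactly (wavelengths written at 17 significant
  digits).
- Nodata: single sentinel (−9999) in cubes and GeoTIFFs, NaN internally in
  elevation grids, propagated through calibration and index math.
- Ground filter degeneracy: clouds whose seeds do not span a plane (e.g.
  one vertical column) are rejected; DTM needs ≥3 ground points.
- Empty masks, unscored panels, and out-of-reach trunks warn and yield
  missing values rather than failing the run.
- Problem sizes in tests and the acceptance script (blocks of 180–500
  vines, 0.05 m DVM cells, 0.1–0.25 m cube cells) were chosen to exercise
  every code path at desk scale; all quantities they report are computed at
  run time.

## Known limitations

The published processing used a proprietary photogrammetry classifier; this
package re-implements an open iterative densification honouring the two
published parameters (0.6 m, 70°), so label-level agreement with the
original tool is not guaranteed. Lat/lon inputs are converted by a local
equirectangular approximation (single-site, metre-scale extents), not a
geodetic library. Cubes are held in memory; no streaming. The
multispectral path shares the index machinery but the synthetic generator
emits hyperspectral cubes only.
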