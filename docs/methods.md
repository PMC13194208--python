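# Methods

## Landscapes and metrics

The unit of analysis is a circular landscape: a buffer of radius *r* around a
sample point, cut from a projected, meter-unit binary raster. A cell belongs
to the landscape iff its **center** lies within *r* of the buffer center
(inclusive) — a simple, reproducible membership rule; fractional cell
coverage is not modeled. A buffer whose circle extends past the raster
extent is refused with an error, never silently truncated, so every computed
landscape is fully observed. Note a geometric consequence: because the
circle must fit inside the extent, corner cells of a raster can never all be
inside one circle, so a landscape always has *outside* cells unless the grid
is tiny.

Within a landscape:

- **Proportion** p = habitat cells / inside cells.
- **Patches** are maximal habitat components under queen (8-neighbor)
  adjacency by default — the common FRAGSTATS convention — switchable to
  rook (4). Labeling is delegated to `scipy.ndimage.label`; the test suite
  cross-checks it exactly against an independent flood fill.
- **Edge density** counts rook-adjacent {habitat, non-habitat} cell pairs,
  both inside the landscape, each contributing one segment of length
  `cell_size`; divided by landscape area in hectares. The circular window
  boundary contributes no edge by default: an edge requires both classes to
  be observed, and the state beyond the window is unknown. A
  `count_boundary` flag adds one segment per habitat side exposed to the
  boundary, for sensitivity analysis.
- **Mean patch size** = habitat area / patch count (ha), defined as 0 when
  there is no habitat. The zero convention avoids an undefined division for
  landscapes that lose all forest and preserves the conservation identity
  `PN x MPS = p x A` (0 = 0); such landscapes stay in the analysis.

An optional pre-filter removes habitat patches of at most `min_patch_cells`
cells (default 0 = off), mimicking the removal of single-pixel
classification noise in satellite products.

Tree-height rasters are binarized at an inclusive threshold (default 5 m,
the FAO forest definition), with an optional non-forest mask (cropland,
built-up, water, snow, ice) forcing cells to non-habitat.

## Composite fragmentation index

For a cohort of landscapes at one radius, each of {patch number, edge
density, mean patch size} is processed in three steps:

1. **Fences.** Quartiles of the *later* year's values (linear interpolation
   between order statistics — the common default; the estimator is
   configurable) give Tukey fences `Q1 - k IQR` and `Q3 + k IQR`, k = 1.5.
   The `lower_fence_sign="plus"` option instead computes `Q1 + k IQR`, a
   variant that appears in some published descriptions of this index; it
   places the lower fence above Q1 and is provided for fidelity comparisons,
   not as the default.
2. **Winsorization.** Values in both years are clamped to the fences fitted
   on the later year, so a single extreme landscape cannot stretch the
   normalization. `capped=False` skips this step (full-range sensitivity
   variant).
3. **Normalization.** Min-max to [0, 1] within each year (per-year bounds of
   the capped values). Because per-year bounds make cross-year level
   comparisons debatable, a pooled-bounds mode normalizes both years against
   their union instead; per-year is the default. A degenerate range
   (constant metric) maps to 0.5, a neutral contribution that neither
   inflates nor deflates the index.

The index is `(PN' + ED' + (1 - MPS')) / 3`, in [0, 1], increasing in patch
number and edge density and decreasing in mean patch area. Fences and bounds
are fitted per radius on the forest-losing cohort only, matching how the
index is used downstream.

## Change classification

Forest loss is `p(t0) - p(t1)`; only strictly positive losses are retained.
Deltas `value(t1) - value(t0)` are oriented so positive always means more
fragmentation (mean patch size multiplied by -1) and classified by sign.
"No change" needs a tolerance for continuous metrics: the default is an
absolute eps of 1e-9 on edge density, mean patch size and the index — small
enough that only genuine ties (identical landscapes, float round-off) fall
in it — while patch number, an integer, always uses eps = 0. Outcome
percentages are tabulated per radius, per 0.2-wide initial-cover bin
(half-open, top bin closed so p = 1 is included), per 0.1-wide loss bin on
(0, 1], and per biome label.

## Synthetic landscapes

The generator emulates the structural features the analysis assumes, not any
particular place: spatially autocorrelated binary habitat at a controlled
proportion, 30-m cells, two time points linked by a loss process, circular
landscapes at multiple radii, and categorical biome strata.

A Gaussian white-noise field is filtered in the Fourier domain with
amplitude `f^(-roughness/2)` — spectral synthesis rather than midpoint
displacement because it is exactly seedable and dimension-agnostic —
and rank-thresholded so exactly `round(p n^2)` cells become habitat
(realized cover within one cell of the target). Roughness 0 is white noise;
values around 2–3 give the aggregated, patchy pattern of real forest cover.

Five loss scenarios remove habitat (never create it), each with a target
removed fraction *f* of the initial habitat:

- **random** — `ceil(fH)` cells uniformly without replacement;
- **erosion** — repeatedly remove the habitat cell with the most rook
  non-habitat neighbors (ties broken in row-major order, so no second
  random stream is needed);
- **patch_removal** — whole patches in increasing size order while the
  cumulative removal stays within the budget; a patch is never split, so
  the realized fraction never exceeds the target and can be 0 (with a
  warning) when even the smallest patch is too large;
- **dissection** — one full row or column strip of width
  `max(1, round(fH/n))`, randomly placed, clipped to the budget;
- **perforation** — cells drawn uniformly from patch interiors (all four
  rook neighbors habitat), recomputed after each removal, until the budget
  is met or no interior remains.

These are designed so their fingerprints are provable: patch removal
strictly decreases patch count whenever it removes anything; each perforated
cell adds four edge segments, so edge density strictly increases; dissection
usually splits patches. The tests verify these signatures over seeded
replicates.

**Cohort defaults** (one decision, then frozen): 500 landscapes of 40x40
30-m cells; cover drawn uniformly on (0.2, 0.8) — the mid-range where
fragmentation change is non-trivial; roughness uniform on (0.5, 3.0)
spanning noisy to aggregated pattern; the five scenarios equally weighted so
no outcome is built in; removed fraction uniform on (0.05, 0.3), matching
the observation that large losses are rare in two-decade windows; radii 250
and 500 m so the default demo stays desk-sized (larger radii only need a
larger grid); the seven forested biome names as strata drawn uniformly.
Per-landscape seeds are `master_seed + index`, so any single landscape can
be regenerated without the rest, and a master seed reproduces every output
byte for byte.

What the generator does **not** emulate: the geographic clustering of real
deforestation, tree-height dynamics and forest gain, mixed loss processes
within one landscape, and registration/classification noise between years.
Passing tests therefore demonstrate the machinery and the qualitative
possibility space (loss can both fragment and de-fragment under every
measure), not the empirical frequencies of those outcomes on real forest
maps.

## Pipeline and I/O

Stages exchange plain CSV so each is independently testable; every output
directory receives a `run_metadata.json` sidecar echoing the configuration
and seed. Rasters are read as Esri ASCII grids (cell size and origin from
the header; suspiciously small cell sizes are refused as likely geographic
degrees) or plain single-band TIFF via tifffile (cell size supplied by the
caller, as plain TIFF carries no trustworthy georeferencing). Reprojection
is out of scope by design: inputs must already be projected in meters.

## Problem sizes

Default test and demo sizes — 20x20 oracle grids (200 per connectivity),
1000 conservation landscapes, 50 scenario replicates at 64x64, and the
500-landscape end-to-end cohort — were chosen as the smallest sizes at which
every property is exercised across its full parameter range; the whole suite
runs in well under a minute.

## Known limitations

- Cell-center circle membership slightly under- or over-counts area relative
  to exact circle/cell intersection; all radii share the bias.
- The edge-density boundary convention differs from tools that count the
  window perimeter as edge; use `count_boundary=True` to compare.
- `dissection` assumes near-square grids when converting the removal budget
  to a strip width.
- The composite index is cohort-relative by construction: values are not
  comparable across cohorts or radii, only within one fit.
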