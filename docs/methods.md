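# Methods

This note documents the models, numerical choices, and limitations behind
`msi2lmd`. It is written for users who need to judge whether the defaults
fit their data, and for maintainers who need to know why things are the way
they are.

## Coordinate frames and affine registration

Four planar frames are chained: the MSI pixel grid (nominally 70 μm pitch),
the optical image of the matrix-covered section, the H&E image of the same
section after staining, and the LMD stage. The convention everywhere is
0-based pixel indices, `x` = column, `y` = row, `y` increasing downward,
with a point denoting the pixel center. This matches raster-image indexing
and makes nearest-neighbor warping unambiguous.

Each hop is a 6-parameter affine map fitted to manually picked landmark
pairs. With exactly 3 non-collinear pairs the two 3×3 linear systems are
solved exactly (zero residual at the landmarks); with more pairs the fit is
the least-squares minimizer of target-space residuals via `numpy.linalg.lstsq`.
Degeneracy is declared when the largest triangle spanned by any three source
landmarks has area ≤ 1e-9 px² (landmark sets are tiny, so the O(n³) check is
free). Affine maps cannot absorb nonlinear tissue deformation from staining;
elastic registration is deliberately out of scope.

### Error model

Per-hop registration error is summarized per axis as the mean and sample SD
(n−1 denominator; SD = 0 for a single landmark) of the **absolute**
landmark deviations, in micrometers. Deviations enter signed; summarizing
their absolute values is a choice — the convention is not dictated by the
error definition itself — and a signed summary can be obtained by
inspecting the deviations directly. The operator-induced picking error is
quantified separately as the mean Euclidean distance between original and
re-registered positions when an image is registered onto itself
(`self_consistency_error`).

Chained errors are propagated as a worst case assuming additive effects:
per axis, means add linearly and SDs combine in quadrature (hops treated as
independent). With the measured per-step errors (7.89±4.06, 1.39±0.33,
3.46±2.62 μm in x; 3.96±4.32, 1.39±0.50, 7.39±3.78 μm in y) this yields
12.74±4.84 and 12.74±5.76 μm — below one 70 μm MSI pixel. Quadrature for
the SDs is an inference from how the combined SD column is structured, and
is asserted in the tests.

Scan resolution converts to pixel pitch as `25400 / dpi` μm (one inch =
25,400 μm): 12,235 dpi → 2.076 μm, 12,189 dpi → 2.084 μm.

## MSI data model and preprocessing

A dataset is a dense `(n_pixels, n_channels)` non-negative matrix with
integer grid coordinates and a strictly increasing m/z axis. Two dialects
are supported: continuous-mode imzML (read and written with `pyimzml`) and
a TSV matrix with an `#mz:` sidecar line, used for human-diffable fixtures.
Absent pixels are simply absent, never zero-filled; duplicate coordinates
are an error.

TIC normalization divides each spectrum by its total ion current so every
row sums to 1 (hence it is idempotent). A unit sum rather than mean-TIC
scaling is the simplest contract consistent with per-spectrum TIC
normalization, and the downstream factorization is insensitive to a global
rescaling of each pixel. Zero-TIC pixels are dropped and the count logged.

Pathologist annotations are polygons in the H&E frame. They are mapped into
the MSI frame through the inverse transform chain and rasterized with the
even-odd (ray-crossing) rule evaluated at pixel centers, with no special
casing of boundary-touching centers. By default the tumor mask is applied
before normalization (`normalize_first` flips the order; the result differs
only in which pixels are present, not in any spectrum's values, since TIC
normalization is per-pixel).

## Segmentation

The tumor spectra are factorized as `X ≈ W H`, `W, H ≥ 0`, by multiplicative
updates minimizing the Frobenius loss — the canonical NNMF algorithm. The
loss trace is recorded per iteration and is non-increasing (a property test
allows 1e-10 numerical slack). Initialization is uniform random, scaled by
`sqrt(mean(X)/k)`, from a seeded generator; 3 restarts are run by default
and the lowest-loss solution kept, making results bit-reproducible per
seed. After fitting, basis rows are normalized to unit L2 norm and the
scores rescaled accordingly, so the arg-max label assignment is not skewed
by arbitrary per-component scaling (the factorization itself is invariant
to this diagonal rescaling). Ties in the arg-max break toward the lowest
component index.

The number of segments is scanned over k = 2..5 and chosen to maximize the
mean silhouette coefficient, computed with Euclidean distance **on the
TIC-normalized spectra** (not the NNMF scores), so the metric space is
identical across k. Singleton clusters contribute silhouette 0 (standard
convention), as does a point with zero distances to everything. For large
inputs the silhouette is evaluated on a seeded subsample of ≤ 2000 pixels;
a k whose labeling collapses to one non-empty cluster is recorded with
silhouette −∞ and skipped; ties prefer the smaller k.

## ROI morphology

The processing order is fixed: smooth → split → remove small → fill holes →
upscale → trace.

- **Smoothing** is a grayscale morphological opening of the integer label
  raster with a 2×2 square. An even-sized element has no center pixel; the
  anchor here is the top-left pixel, with the dilation using the reflected
  element so the opening is anti-extensive and idempotent. Opening the
  label raster directly means the result can depend on the numeric order of
  labels where three or more segments meet; per-segment binary opening can
  be substituted by opening each mask from `split_segments`.
- **Small-area removal** deletes 4-connected components of ≤ 30 pixels
  (keep threshold 31), i.e. sub-region specks not worth cutting.
- **Hole filling** turns background components that are 8-connected and do
  not reach the image border into foreground. Note the connectivity mix —
  4-connected foreground for the area filter, 8-connected background for
  holes, 8-connected foreground for tracing — which follows the classic
  raster-morphology conventions of the corresponding named routines.
- **Upscaling** to the histology raster uses nearest-pixel inverse mapping:
  each target pixel center is pulled back through the inverse transform and
  rounded with `floor(v + 0.5)` per axis (0.5 always rounds up; bit-exact
  tests depend on this tie rule, which also governs the integer rounding of
  exported coordinates).
- **Boundary tracing** is Moore-neighbor tracing (clockwise, starting at
  each component's raster-first pixel with its west neighbor as backtrack,
  stopping when the walk is about to repeat its first move from the start).
  It yields one closed polygon of boundary-pixel coordinates per
  8-connected component; interior holes are ignored, as the cutting laser
  follows outer contours. A single-pixel region yields the degenerate
  closed polygon `[(x, y), (x, y)]`.

## LMD export

The instrument imports shapes from XML together with three calibration
(teaching) points that the operator re-selects in the live image. All
coordinates are re-expressed relative to the first teaching point (the
origin maps to (0, 0)) and rounded to integers; translation preserves
pairwise vertex differences exactly, so rounding distorts each vertex by at
most 0.5 units per axis. The element vocabulary (`ImageData`,
`GlobalCoordinates`, `X/Y_CalibrationPoint_i`, `ShapeCount`, `Shape_i` with
`PointCount` and `X_j`/`Y_j`) follows the Leica LMD import convention and
is frozen so golden-file tests are byte-exact; serialization is
deterministic. Coordinates are emitted y-down (image convention); a
`flip_y` option mirrors the axis for instruments expecting y-up, since the
instrument's convention is not universal. Units are optical-image pixels
relative to the origin; physical units can be derived via the frame's pixel
size.

## Microproteomics statistics

QC-flagged rows (decoy "reverse" hits, "only identified by site",
"potential contaminant") are removed first; a row carrying several flags is
removed once but counted under each flag in the report. LFQ intensities of
0 are treated as missing rather than log2(0); rows with fewer than
`min_valid` (default 2) finite values are excluded and reported — the exact
validity filter used upstream of published tables is generally not
recoverable, which is why it is a parameter. Remaining rows are
log2-transformed and z-scored per protein with the sample SD (n−1);
`ddof=0` gives the population-SD variant. Constant rows get z = 0 and are
flagged.

A protein is called exclusively over-expressed in segment `s` when
`z(s) ≥ +1` and all other segments are below the bound (under-expression
symmetric at −1); crossing the bound in two or more segments voids the
call.

**A structural caveat with three segments.** Row-wise z-scores of n values
satisfy `Σz = 0` and `Σz² = n−1`, so with n = 3 the attainable |z| maximum
is 2/√3 ≈ 1.1547 — and, less obviously, *every* non-constant row reaches
+1 or −1 (two values ≥ 1 are impossible, so any crossing is automatically
exclusive). Threshold 1 therefore calls every protein whose three values
are not identical; only (near-)constant rows escape. A threshold of 1.2 is
unattainable and yields zero calls. Both facts are asserted as properties.
Consequently, with three segments the selectivity of the ±1 rule rests
entirely on how many rows are effectively constant across segments, and
small published call counts are not reproducible under a strictly row-wise
reading; per-column standardization behaves differently and is a plausible
alternative reading of the upstream tooling. The row-wise contract is
implemented as specified and the phantom's non-planted proteins are
generated constant-across-segments (plus optional exchangeable noise) so
that planted-marker recovery is exact in the noise-free case.

Protein ordering uses seeded k-means pre-clustering (default 300 clusters,
10 iterations, 1 restart, random centroid init) followed by complete-linkage
Euclidean agglomeration of the centroids (scipy); each protein inherits its
centroid's leaf position, keeping original order within a centroid. With
one pre-cluster per row the k-means step is a no-op and the linkage equals
a plain complete-linkage clustering (tested against a brute-force
agglomeration). The dendrogram is exportable as Newick.

## Phantom generators

The phantoms define the synthetic study conditions and are pure functions
of their parameters and seed:

- **MSI phantom** — a `(40, 40)` grid at 70 μm pitch by default, 60
  channels spanning m/z 350–1600, partitioned into `k_true = 3` contiguous
  regions (Voronoi cells of seeded centers, hence convex and contiguous).
  Each region's signature is a shared low baseline (0.2–0.3) plus a few
  region-exclusive peaks of amplitude ~`signature_separation` (default 5),
  with truncated Gaussian noise (`noise_sd` 0.5, clipped at 0 to preserve
  non-negativity). Sparse, disjoint peak sets make the factorization
  identifiable at this separation-to-noise ratio (~10).
- **Registration phantom** — fiducial/landmark coordinates in each frame
  related exactly (or with seeded Gaussian jitter) by ground-truth
  transforms; the default MSI→optical transform uses the physical ~33.6×
  pitch ratio plus a small shear and offset, optical→H&E a small rigid-ish
  motion. Raster images with drawn fiducial discs are provided for
  completeness.
- **Protein phantom** — 1040 proteins × 3 segments by default;
  `planted_per_segment` over- and under-expressed markers per segment get
  one segment's log2 intensity shifted by ±`effect_size`; all other
  proteins are expressed equally across segments, with optional
  exchangeable log-scale noise (default 0, see the caveat above).

What the phantoms do **not** emulate: realistic lipid spectra (peak shapes,
correlated channels, baseline drift), histological texture, staining-induced
tissue deformation (the ground-truth chain is exactly affine), intensity
gradients across the section, and the correlation structure of real LFQ
data. Passing tests therefore demonstrate the correctness of the
computational chain under its own model assumptions — exact affine
geometry, separable spectral signatures — not robustness to these real-data
effects.

## Problem sizes and determinism

Default test and acceptance problem sizes (40×40 and 30×30 grids, 60
channels, ≤ 1040 proteins, 1250² upscale rasters) were chosen so the full
suite runs in well under a minute while keeping every planted structure
comfortably recoverable; they are not tuned to any particular hardware.
All randomness flows through explicit integer seeds (numpy `default_rng`);
NNMF restarts draw child seeds from the base seed, so every reported number
is bit-reproducible.

## Known limitations

- Affine-only registration; staining deformation is unmodeled.
- Grayscale opening on the label raster is label-order dependent at triple
  junctions (see above).
- The ±1 exclusivity rule with three segments is structurally permissive
  (see the caveat); with ≥ 4 segments it regains selectivity.
- The LMD XML dialect covers the shape-import subset only (no
  cutting-parameter management, which is an instrument-side concern).
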