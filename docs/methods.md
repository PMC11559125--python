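# Methods

## The stitching model

A Visium *group* is a set of capture areas measured from one tissue block
and meant to be analysed as one sample. Each area arrives with SpaceRanger's
spatial bundle: a spot table (`tissue_positions.csv`, barcode, `in_tissue`,
hexagonal `array_row`/`array_col`, fullres pixel coordinates), scale
factors, and downscaled images. Stitching itself — deciding how the areas
sit relative to each other — is done interactively in an image tool and is
deliberately *not* automated here: physical gaps (score lines) make purely
data-driven registration ill-posed. The input `spotstitch` consumes is the
per-area **rigid affine transform** (rotation + translation, |det| ≈ 1)
that the stitching session produced, in TrakEM2's `matrix(a,b,c,d,tx,ty)`
parameter order (column-major linear part), or as a plain whitespace table.

### Uniform rescaling

Hires images from different areas need not share a physical pixel size. For
spot diameter `d_i` (fullres px) and hires scale factor `h_i`, each area is
rescaled by `s_i = (max_j d_j)(max_j h_j) / (d_i h_i)`. The formula is
implemented exactly in this factored form. Note that when the maxima of `d`
and `h` come from *different* areas this differs from normalising by
`max_j (d_j h_j)` and yields `s_i > 1` for every area; the alternative is
available via `compute_rescale_factors(..., use_product_max=True)`. The
default keeps the factored form because it is the definition the rest of
the coordinate pipeline is calibrated against.

### Coordinate transformation

Translations in the affine are expressed in the rescaled-hires pixel space
the stitching tool displayed. Fullres spot coordinates are therefore
*lifted* into that space (multiply by `h_i·s_i`), transformed, and
*projected* into the group fullres coordinate space (divide by
`h_ref·s_ref`), where the **reference area** is the one with maximal
`d_i·h_i` — the coarsest physical resolution, so no area's data is
projected above its native scale. The net per-area scalar
`(h_i·s_i)/(h_ref·s_ref)` is what makes distances-per-pixel identical
across areas: after the transform, the median nearest-neighbor spot
distance agrees across areas to 1e-6 relative. A point is always treated as
`(x, y) = (pxl_col_in_fullres, pxl_row_in_fullres)`, with the row axis
increasing downward as in image coordinates.

Only `in_tissue == 1` spots enter a stitched sample by default
(`in_tissue_only=False` keeps everything); out-of-tissue spots carry no
usable expression and would dilute the overlap statistics.

## The artificial hexagonal array

Original array coordinates cannot survive stitching: areas are rotated and
translated, and their index ranges collide. A fresh Visium-like lattice is
built over the whole group:

* **pitch**: `pitch_px = d_ref · (100 µm / 55 µm)` — the platform's 100 µm
  center-to-center spacing expressed through the 55 µm spot diameter. The
  55 µm constant is exposed as a parameter (`spot_diameter_um`) for
  non-standard chemistry.
* **anchor**: the lattice origin is the minimum x and minimum y over all
  transformed spot coordinates, i.e. lowest pixel row ↔ `array_row` 0 and
  lowest pixel column ↔ `array_col` 0, the standard SpaceRanger axis
  pairing. (Descriptions of this anchoring sometimes cross the two axes in
  a way that would map a minimum *and* a maximum to 0 simultaneously; the
  conventional pairing is used and documented here instead.)
* **indexing**: `array_col` steps half a pitch in x, `array_row` steps
  `pitch·√3/2` in y, and valid points have equal row/column parity — so
  consecutive spots within a row are two columns and one pitch apart,
  exactly as on a real slide. Index ranges grow as needed and generally
  exceed a single area's 0–77 / 0–127.

Every spot receives the indices of its Euclidean-nearest lattice point. The
implementation enumerates the few candidate lattice points around each
spot's fractional lattice coordinates and is tested to be exactly
equivalent to brute-force search over all lattice points; exact ties are
broken to the lowest row, then lowest column, for determinism. For spots
inside the lattice hull the assigned distance is bounded by the hexagonal
Voronoi circumradius `pitch/√3`.

Multi-occupancy is legal and intended: spots from different areas at the
same tissue location share one array position, which is what lets hex-grid
neighbor queries (the six offsets `(±1, ±1)` and `(0, ±2)`) see across
capture-area seams — an interior spot in a doubly-occupied region has
twelve unique neighbors at six unique array coordinates.

## Overlap handling

**Definition.** Two spots overlap iff they are assigned the same artificial
array position. This is the operational definition downstream clustering
experiences; a geometric alternative (cross-area pixel distance <
pitch/2, with contested sets formed as connected components) is available
behind `distance_overlap=True`.

**Exclusion for plotting.** Whole capture areas are ranked by mean UMI per
spot; at each contested position the spots of the highest-ranked present
area keep `exclude_overlapping = False` and all others get `True`. Ranking
whole areas (rather than picking winners per position) keeps plots from
speckling between areas. Exact mean ties retain the lexicographically
smaller area id. When three or more areas contest one position the same
global ranking applies. No spot is ever dropped — the flag is advisory.

**Merging.** `merge_overlapping` produces at most one spot per occupied
array position: counts are the elementwise integer sum over contributors
(the grand total is conserved exactly), the merged spot sits at the lattice
centroid, `in_tissue` is 1 if any contributor's is, and a provenance column
lists the contributing barcodes.

**Agreement.** `overlap_label_agreement` is the fraction of unordered
cross-area spot pairs at shared positions whose cluster labels agree. It
counts *pairs*, not positions — a position contributed by three areas
yields three pairs, weighting multi-overlaps naturally. It is undefined
(`None`) without overlap pairs; under labels drawn independently and
uniformly over k clusters its expectation is 1/k, which the tests verify to
within three standard errors.

## The synthetic study design

The fixture generator emulates a three-area design: two areas overlapping
by a configurable fraction of their width (default 50%) and a third across
a small gap (default 2 pitches), rotated 180°. All areas are sampled from
one global tissue field: a vertical two-region step (a white-matter-like
and a cortex-like region) with Poisson expression over a six-gene panel —
per-region marker means 2.0 inside / 0.1 outside, housekeeping mean 1.0 —
so overlapping regions carry correlated expression and the planted region
labels are transform-consistent. Per-area depth factors (1.1, 0.9, 1.0)
make the mean-UMI exclusion ranking decidable.

Defaults mirror a real capture area: a 78 × 128 equal-parity array (4,992
spots), and a hires image under the 2,000 px cap. The horizontal offset
between the overlapping areas is rounded to an even number of array columns
so nominal spot positions in the overlap coincide *exactly*; the ground
truth lists those coincident cross-area pairs and every spot's region
label. Written pixel coordinates add uniform per-axis jitter of pitch/10
(always below the pitch/4 bound under which co-assignment of coincident
spots to one lattice cell is guaranteed), so transformed spot centroids
scatter realistically at overlaps while ground truth stays exact.

What the generator does **not** emulate: histology-realistic imaging (the
hires PNG shows region-colored spot disks plus three dark landmark blobs
for visual transform checks), sequencing-depth gradients, spatial
autocorrelation beyond the region step, barcode sequence realism, or
non-rigid distortion between areas. Passing tests therefore demonstrate the
geometry, bookkeeping and statistics of stitching — not robustness to
imaging artifacts or to misestimated transforms, which on real data come
from the interactive stitching session.

## Numerical and design choices

* Affine determinants outside [0.99, 1.01] warn rather than fail (users do
  apply slight scaling); singular linear parts are errors.
* Image resampling is bilinear; downscaling to the lowres target adds an
  anti-alias prefilter, upscaling does not. Resizing an already-target-size
  image is an exact no-op.
* The group lowres target is 1,200 px on the longest side — 600 px (the
  SpaceRanger lowres cap) per area for a square 2×2 group — and is
  configurable (`target_longest`) for other layouts. The written
  `tissue_lowres_scalef` relates group fullres coordinates to lowres
  pixels; `tissue_hires_scalef` relates them to the stitched composite.
  For very small composites the lowres "down"-scale can exceed the hires
  scale; this inversion is warned about, not rejected.
* Stitched barcodes are made globally unique by suffixing the capture-area
  id (`AAAC...-1_A1`), since every area shares one barcode whitelist.
* Position files are written with 6-decimal pixel coordinates; round trips
  are exact at that precision.
* Test and acceptance problem sizes: the unit suite exercises 16–24-column
  areas (hundreds of spots) where exhaustive oracles are cheap; the
  acceptance script runs the full 78 × 128 three-area design (14,976
  spots), a size at which every geometric property above is measured at the
  platform's real array dimensions.

## Known limitations

* Rigid (affine) transforms only; no non-linear deformation, no automatic
  registration, no cross-technology alignment.
* MatrixMarket count bundles only (no HDF5 feature-barcode matrices).
* Full-resolution microscopy images are out of scope end to end; the
  pipeline operates on SpaceRanger's ≤ 2,000 px hires derivatives.
* The square-grid layouts of Visium HD / legacy ST are not modelled; the
  lattice construction would extend to square grids naturally.
* Exact numeric agreement with any other implementation of the
  lift–apply–project composition is not claimed where that implementation's
  scaling order is undocumented; the contract here is the measurable one
  (uniform distances-per-pixel across areas).
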