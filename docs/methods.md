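# Methods

`fibrometry` quantifies macerated wood cells — fibers (long, thin) and
vessels (shorter, wider) — from instance-segmentation output of brightfield
macerate microscopy. The package does not segment: any backend that emits
per-instance masks or polygons (with confidences) plugs in. What it does is
everything around segmentation: annotation format handling, per-instance
morphometry, detection/segmentation evaluation, group statistics, and a
synthetic scene generator that provides exact ground truth so the whole
chain is testable without microscope data or a trained network.

## Morphometry

Every instance is measured independently on its full binary mask. Macerated
cells are translucent, so overlapping cells each keep their complete mask
and shared pixels contribute to both — no measurement ever subtracts one
instance from another.

**Length.** The mask is thinned to a single-pixel skeleton with the
Zhang–Suen parallel algorithm (sub-iteration 1 removes south/east boundary
pixels, sub-iteration 2 north/west, both evaluated on the image state at
the start of the sub-iteration, iterated to a fixpoint). Thinning preserves
the connectivity of each component and never adds pixels. The skeleton's
*longest path* is then extracted by double breadth-first search on the
8-connected skeleton graph: BFS from an arbitrary pixel finds the farthest
pixel *u*; BFS from *u* finds the far end and the path. This is exact on
acyclic skeletons (the usual case) and a well-behaved heuristic when the
skeleton contains loops (e.g. vessels with perforation plates); an
exhaustive all-pairs mode is available for skeletons under ~10⁴ pixels.
Using only the longest path means side branches from thinning artifacts do
not inflate length. Ties (equidistant far pixels) are broken
lexicographically by (row, column) so results are reproducible.

Three length modes:

- `pixel_count` (default): number of pixels on the longest path. This
  mirrors pipelines that sum the thinned mask, but a diagonal step advances
  √2 px while counting 1, so obliquely oriented cells are undercounted —
  by up to 29% at 45°, about 9–11% on average over random orientations.
- `weighted_path`: sum of step lengths (1 axial, √2 diagonal) along the
  longest path. Orientation-unbiased; this is the mode the validation
  experiments use when comparing to physical ground truth.
- `pixel_count_all`: count of all skeleton pixels including branches, for
  comparison with summation-based implementations.

The skeleton graph deliberately keeps plain 8-adjacency: thinning leaves
occasional redundant corner pixels on oblique runs, and letting the path
step diagonally past them keeps the weighted length close to the geometric
curve length (forcing the path through every corner pixel inflates it by
several percent).

**Width.** The exact Euclidean distance transform assigns each foreground
pixel its distance to the nearest background pixel; the mask is padded by
one background pixel first so tightly cropped instances still get finite
distances. The maximum of the transform is the half-thickness at the
thickest point, and the reported width is twice that maximum. Because
distances run between pixel *centers*, this overestimates the true band
width by about one pixel; a bias-corrected mode (2·max − 1) is available
behind `width_bias_correction`, default off so the default numbers match
the common 2·max convention.

**Area.** Shoelace area of the source polygon when the instance came from a
polygon annotation (contour-area semantics); foreground pixel count for
mask-only input. Both are exposed.

**Calibration.** Pixel measures convert to microns with `um_per_px`
(default 0.65, the pixel size of the reference 10× imaging setup); areas
use its square. `length_um / length_px == um_per_px` holds exactly for
every record.

**Border exclusion.** An instance whose mask (or polygon vertex) comes
within `border_margin` pixels (default 0 = strict touch) of the image
border is flagged: partially imaged cells are biased short. Flagged records
are written to the per-instance CSV with `excluded = True` and skipped by
summary statistics. The test is always evaluated on the *global* image
frame, never on tile frames.

## Rasterization and annotation geometry

Pixel (r, c) has its center at continuous (x=c, y=r). A pixel is inside a
polygon iff its center passes the even-odd (ray crossing) test; centers
exactly on an edge count as foreground (deterministic tie-break).
Self-intersecting polygons are resolved by the same even-odd rule,
consistent with absolute shoelace areas. Degeneracy means all vertices
collinear — a self-intersecting polygon with zero *signed* area can still
have positive coverage and is rasterized normally.

Large images are tiled (default 1024-px tiles, 10% overlap — the overlap
convention of tiled microscope acquisition) rather than resized, preserving
the micron calibration. Windows cover every pixel; the last row/column is
shifted inward so no window leaves the image.

## Tiled measurement and de-duplication

When a backend runs per tile, each cell near a tile boundary may be
detected multiple times, or only partially. The merge step shifts all
detections to global coordinates, then:

1. detections touching an *interior* tile edge (an edge that is not also
   the global border) are fragments;
2. complete detections are de-duplicated greedily by descending confidence:
   a same-class pair with mask IoU ≥ `iou_dedup_threshold` (default 0.8)
   collapses to the higher-confidence copy. Genuinely distinct overlapping
   cells rarely exceed 0.5 IoU while re-detections of one cell exceed 0.9,
   so the threshold separates the two regimes;
3. fragments covered (intersection over the fragment ≥ threshold) by a kept
   complete detection are absorbed; uncovered fragments are flagged
   `fragmented` and excluded from measurement, with counts logged.

For any instance complete within at least one tile, tiled measurement is
exactly equal to whole-frame measurement — the validation suite asserts
record-level identity.

## Detection/segmentation evaluation

Mask IoU (bounding-box IoU available for detection-style curves), greedy
confidence-ordered matching (ties by instance id), each prediction taking
the unmatched same-class ground truth of highest IoU ≥ threshold. Ground
truths are independent even when their masks overlap; a cell is never
unmatchable because another cell lies on top of it. True negatives are
undefined for instance detection and reported as not-applicable.

P = TP/(TP+FP) (1.0 with no predictions), R = TP/(TP+FN), F1 = 2PR/(P+R).
Average precision uses 101-point interpolation (precision at recall r = max
precision at any recall ≥ r, averaged over r ∈ {0, 0.01, …, 1}), the COCO
convention of the segmentation-model ecosystem; exact continuous
integration of the same envelope is available behind a flag and agrees
within 0.01. mAP50 averages per-class AP at IoU 0.5; mAP50–95 averages over
IoU ∈ {0.50, 0.55, …, 0.95}. Classes absent from the ground truth are
excluded from the means. The F1–confidence curve sweeps 101 cutoffs and
reports the argmax.

## Group statistics

Summaries (mean, sd, median, quartiles by linear interpolation between
order statistics — the common plotting default, stated explicitly because
boxplot conventions differ) are computed over non-excluded records. The
two-group comparison is the two-independent-samples t statistic
t = (X̄₁ − X̄₂)/SED with the pooled-variance Student form by default
(matching `scipy.stats.ttest_ind`'s default, which the measurement
ecosystem commonly calls); Welch's form (`equal_var=False`, df by
Welch–Satterthwaite) is exposed and preferable for unequal group sizes or
spreads. P-values are two-sided by default. Percent change is
100·(mean_test − mean_ref)/mean_ref with the reference group first.

## Synthetic scenes

Each cell is a constant-width **stadium**: a disk of diameter w swept along
a quadratic Bézier centerline, so true length (arc length), width, and area
(L·w + π(w/2)²) have closed forms. The control point's perpendicular offset
is bounded by `curvature`·length (default 0.15, max 0.3); the chord is
rescaled iteratively so arc length matches the requested length within 2%;
the polyline is discretized at ≤ 0.5-px steps. Rasterization uses exact
point-to-segment distance (pixel center within w/2 of the centerline),
accumulated over a local window per segment of a 2-px resampling — at the
generated curvatures the 2-px chords deviate from the curve by well under
0.01 px. Placement is rejection-sampled fully in-frame (up to 100
attempts); a flag disables rejection to generate border-touching cases.

Size defaults are scaled from typical aspen macerate averages (fibers
~310 µm × 23 µm, vessels ~247 µm × 51 µm) at 0.65 µm/px: fiber length
log-normal with mean 460 px, sd 120 px and width normal (35, 5) truncated
at 3 px; vessels log-normal (380, 80) and normal (78, 8). Log-normal
parameters are given as the mean/sd of the length itself, not of its log.

Optics: bright field at mean gray 0.92 of full scale with per-pixel
Gaussian noise (sd 0.02); each covering cell multiplies transmitted light
by exp(−absorbance) per channel with a mild class tint (Beer–Lambert
stacking), so doubly covered pixels are darker than singly covered ones
while every instance's full mask is stored un-occluded. Scenes are
byte-identical for identical (spec, seed).

What the generator does **not** emulate: fiber tapering toward the tips,
cell-wall texture and lumen, stain chemistry, point-spread blur, debris,
and broken cells. Passing validation therefore demonstrates correctness of
the measurement chain on known geometry, not segmentation robustness on
real slides.

## Validation experiments and problem sizes

All experiments live in `fibrometry.validation`, derive every random draw
from one seed, and are re-run by `scripts/acceptance.py`:

- **Parameter recovery** — 8 default-parameter scenes of 1600² px with 25
  fibers + 25 vessels each (200 per class); weighted-path mean length
  within 5% of the realized ground-truth mean, mean width within 2 px.
  The residual length error (≈ +3–4%) is the staircase overestimate of
  digital curves minus tip erosion by thinning.
- **Scale invariance** — (a) default scene measured whole vs through
  1280-px tiles at 50% overlap: records identical; (b) 20 repetitions of
  two independent 1280² fields with 100 fibers each, pooled t-test on
  measured lengths: p > 0.05 expected in ≥ 18/20 (nominal rate 95%).
- **Calibration** — 2,000 null pairs (n = 50 per group) drawn from the
  fiber-length distribution: type-I error within [0.035, 0.065] at
  α = 0.05; 20 repetitions of a planted +12% mean-length shift at
  n = 500 per group: p < 10⁻⁴ in ≥ 19/20.
- **Perfect-prediction evaluation** — ground truth evaluated against
  itself on a 9-instance scene: mAP50 = mAP50–95 = 1.0 exactly.

## Known limitations

- `pixel_count` length is orientation-biased by construction; use
  `weighted_path` when absolute lengths matter.
- Width is a maximum-inscribed-disk diameter: for a cell with a swollen
  midpoint it reports the swelling, not a typical width.
- The longest-path heuristic can shorten measured length on skeletons with
  large loops; the exact mode is O(n²) in skeleton pixels.
- The tiled path only guarantees equality with whole-frame measurement for
  instances complete in at least one tile; cells larger than the tile
  stride are flagged `fragmented` and dropped rather than stitched.
- The generator's stadium geometry makes true width exactly constant along
  the cell; real tapering would lower measured mean width relative to the
  generator's truth.
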