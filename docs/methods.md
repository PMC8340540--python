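# Methods

## Problem setting

A boundary predictor maps an image to a gray-scale *boundary* map: pixel
intensity in [0, 255] encodes edge confidence, 0 is background, and true
contours appear as ramps several pixels wide. Downstream uses (contour
metrology, tracking, evaluation against 1-pixel ground truth) need a
*thin edge*: binary, one pixel wide, 8-connected. `thinedges` implements
the extraction function `E(g; α, β, γ)` and everything needed to tune and
evaluate it. Conventions throughout: (row, col) indexing, 0-based, origin
top-left; the 4-neighborhood is {N, S, E, W}; the 8-neighborhood adds
diagonals; binary maps are stored on disk as {0, 255} PNGs.

## Gray-weighted distance transform (GWDT)

For a foreground pixel (i, j), the GWDT is the minimum over all
4-connected pixel paths from (i, j) to a background pixel of the summed
intensities along the path; the start pixel and every intermediate
foreground pixel contribute, the terminal background pixel contributes 0.
Background maps to 0.

Numerical and structural choices:

* The transform is **exact**, computed by multi-source Dijkstra
  propagation seeded at all foreground pixels 4-adjacent to background.
  Two-pass raster-scan approximations were deliberately excluded: the
  ridge extraction that follows is sensitive to cost errors on crests.
* Costs are exact integers (sums of 8-bit values), so there is no
  floating-point drift and results are bit-identical across platforms.
* Image borders are **not** background. A path must end at an in-image
  zero pixel; an image with no zeros raises `DegenerateImageError` rather
  than silently padding. Callers that sweep parameters (the grid search)
  catch this and score the offending image as empty.

## Eight-way neighborhood number

For a 3×3 neighborhood with neighbors x1..x8 numbered counterclockwise
from East (x1=E, x2=NE, …, x8=SE, and x9 ≡ x1), the neighborhood number is

    N_c = Σ_{k∈{1,3,5,7}} ( x̄_k − x̄_k·x̄_{k+1}·x̄_{k+2} ),   x̄ = 1 − x.

N_c counts the 8-connected groups of foreground around the center: a
pixel with N_c = 1 is *simple* — deleting it neither splits nor merges
local foreground — while endpoints score ≤ 1 with fewer than two
neighbors, lines score 2, crossings more. Positions outside the image are
treated as background. The implementation is verified exhaustively
against a literal transcription of the formula over all 256
configurations.

## Gray-weighted path skeletonize (GWPS)

GWPS extracts the ridge of the GWDT surface as ordered homotopic
thinning:

1. Enqueue every foreground pixel keyed by `(cost, row-major index)`.
2. Pop in ascending order; delete the pixel iff it is still foreground,
   `N_c = 1`, and it has ≥ 2 foreground 8-neighbors.
3. After a deletion, re-enqueue the surviving 8-neighbors.
4. Stop when the queue empties.

Low-cost flanks are peeled away first, so the surviving set tracks the
high-cost crest; the deletion rule guarantees the output support is a
subset of the input, the number of 8-connected components is preserved,
and no deletable pixel remains (hence idempotence). The row-major
tie-break makes the procedure fully deterministic. Endpoint preservation
(the ≥ 2-neighbor condition) is essential: without it open curves erode
from their tips. Its side effect — spurs from small boundary
irregularities survive thinning — is intentional; spur removal is the
pruning stage's responsibility. One known consequence of the pure-N_c
rule is that 2×2 foreground blocks are locally undeletable and can
survive in pathological inputs; on ramp-shaped cost surfaces they do not
arise.

The `'2D'` (Zhang–Suen) and `'3D'` (Lee) baselines are published
algorithms dispatched to `skimage.morphology.skeletonize`; the 3-D
variant runs on the binarized image embedded as a single-slice volume.
They ignore intensity entirely, which is exactly the contrast GWPS is
designed to beat on asymmetric ramps.

## Spur pruning

The limit is `l = (γ/100)·√(w²+h²)` pixels — relative to the image
diagonal so pruning strength is comparable across image sizes. A branch
is walked from each endpoint (exactly one foreground 8-neighbor); its
length is the pixel count up to, but excluding, the junction, compared as
`length ≤ l` with `l` real-valued. Removal iterates to a fixed point,
removing the shortest branch first (row-major tie-break), since removing
one spur can expose another. Whole open curves, closed loops and isolated
pixels are exempt: pruning targets artifacts hanging off an edge, never
the edge itself. Junction pixels are always retained; a junction that
drops to two neighbors simply stops being one.

Junction detection on 8-connected skeletons has a subtlety: the base
pixel of a spur attached to a straight run is diagonally adjacent to
several run pixels, so a naive "≥ 3 neighbors" test places the junction
one pixel too early (and, worse, makes the run's own pixels look like
junctions). The walk therefore clusters the unvisited pixels ahead of it
by mutual 8-adjacency: one cluster of ≥ 3 means the walk has hit the
flank of a run (the current pixel is the spur's base and belongs to the
branch); ≥ 2 clusters mean the current pixel is itself the junction
(excluded and kept); a single mutually-adjacent pair is just the curve
stepping around a corner and the walk continues through the 4-adjacent
member. A consequence worth noting: a 1-pixel orthogonal stub off a line
has three 8-neighbors, hence no endpoint, and is not a spur under this
definition — it is invisible to pruning.

## Metrics

**SDE** — after replacing an empty map by a single pixel at
`(⌊h/2⌋, ⌊w/2⌋)`, the score is the mean Euclidean distance from predicted
pixels to the nearest ground-truth pixel averaged with the mean distance
in the opposite direction. The two directions penalize spurious and
missing edges respectively, so the score integrates precision- and
recall-like errors; it is symmetric, non-negative and zero iff the pixel
sets coincide. Distances come from an exact Euclidean distance transform;
no sign (inside/outside) is tracked, since both operands are thin curves.
The center-pixel correction is applied inside the metric only — saved
edge maps are never mutated — and gives a finite, size-aware penalty when
one side predicts nothing.

**IoU-box** — inclusive-pixel axis-aligned bounding boxes of the
8-connected components on each side are matched greedily in descending
pairwise IoU (ties broken by component indices), one-to-one so a single
sprawling prediction cannot score against many ground-truth components;
the score is the mean over ground-truth components of the matched IoU,
unmatched components scoring 0.

Aggregation over image sets reports mean, median and *population*
standard deviation per metric, with CSV/JSON export.

## Parameter search

`grid_search` evaluates every (α, β, γ) in a `SearchGrid` — iterating α
outer, β middle, γ inner, each in declared order — computing mean SDE and
mean IoU-box over the validation pairs, and returns the first-encountered
minimizer of mean SDE (IoU-box is reported, never used for selection).
The full table is returned so callers can inspect ties. Thresholding and
skeletonization are cached per (α, β) and reused across γ, which cannot
change results since only pruning depends on γ. A per-image degenerate
failure (no background under GWPS) scores that image as empty rather than
aborting the sweep.

The default grid steps α by tens (0–250; 255 is unreachable by the
stepping and excluded, though a user grid may include it), takes all
three β methods, and γ over every integer 0–10 plus tens 20–100 — 26 × 3
× 20 = 1560 combinations, a deliberate coarse-but-affordable compromise;
finer grids are a drop-in `SearchGrid`.

## Synthetic data

The generator emulates a boundary predictor's output around a known
answer. A smooth random curve — an open spline (a wavy, monotone-in-x
cubic through 4–6 random control points) or a jittered closed ellipse —
is rasterized to an 8-connected 1-pixel chain ≥ 2 px inside the border
(consecutive rounded samples joined by Bresenham lines, then redundant
corner pixels removed until the chain is minimal). The boundary image is
`round(A·exp(−d²/2σ²))` of the Euclidean distance d to the curve, zeroed
below 1, then degraded per configuration: *gaps* remove a run of curve
pixels per curve segment long enough (relative to σ and A) that the
rendered intensity decays to zero inside the gap, splitting the blob;
*irregularities* grow short random stubs off the curve before rendering,
which thicken the ramp locally and reliably induce skeleton spurs;
*noise* is additive Gaussian, clipped to [0, 255] and rounded. All
randomness flows through `numpy.random.default_rng` seeded from the
config (dataset sample k uses seed + k), so generation is deterministic.

Defaults — 96×96 px, σ = 2, peak A = 200, noise σ = 8, no gaps, no
irregularities — model a confident predictor at moderate resolution, with
noise kept well below useful α values so parameter recovery is
well-posed. What the generator does *not* emulate: textured backgrounds,
intensity varying along the contour, correlated (structured) noise,
multiple interacting objects, or any specific predictor's error
distribution. Passing tests on this data demonstrate the correctness and
calibration of the *post-processing*, not performance on any real imaging
domain.

## Verification sizes

The test suite and `scripts/acceptance.py` run entirely on generated
data: 200 random 16×16 images for exact GWDT-vs-Dijkstra agreement, all
256 neighborhood configurations, 100 noisy 64×64 boundaries for GWPS
topology/idempotence, 50 clean 96×96 ramps for ridge recovery (mean
distance to ground truth ≤ 1 px; end-to-end mean SDE ≤ 2 px), 100
spur-implanted skeletons for the pruning postcondition, and a 3×3×2 grid
on five 64×64 pairs for search-vs-oracle agreement — sizes chosen to
exercise every code path while keeping a full run in seconds on one core.

## Known limitations

* GWPS ridge placement on perfectly flat cost plateaus is resolved by
  the deterministic scan-order tie-break, which can bias the ridge
  toward lower row/column indices by up to a pixel.
* Pruning length is a pixel count, not arc length: diagonal steps count
  1, so a diagonal spur of geometric length l·√2 is removed at limit l.
* The SDE and IoU-box definitions here are one concrete choice within a
  family of distance/box metrics in the literature; absolute values are
  comparable only within this package's convention.
* The search is exhaustive over its grid; no early stopping or
  continuous refinement is attempted.
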