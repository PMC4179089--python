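# Methods

## Detection model

A grayscale sample image `f` (M×N, row-major, 0-based, origin top-left) is
scanned in valid mode by each K×L template `ω` of a library: the correlation
surface has shape (M−K+1)×(N−L+1) and `(i, j)` indexes the window whose
top-left corner is at row `i`, column `j`. The NCC score subtracts the
window and template means and normalizes by both deviation energies, so it
is invariant to affine intensity maps of either image — the property that
makes the detector robust to background gradients and illumination drift.

Two code paths compute the same quantity. `ncc_at_point` evaluates the
definition directly at one offset and serves as the in-package reference;
`ncc_surface`/`max_over_library` compute whole surfaces using one
cross-correlation per template for the numerator (the template is made
zero-mean first, which makes the window-mean term vanish) and integral-image
window sums for the denominator. Sums accumulate in float64; the fast path
agrees with the reference to better than 1e−6, which the test suite checks
against an independently written per-pixel oracle and against
`skimage.feature.match_template`.

Degenerate windows: where the sample window's deviation energy is ≤ 1e−10
the score is defined as 0 rather than NaN — a constant window carries no
shape information, and 0 is the "unrelated" value of the NCC scale. Computed
values are clipped into [−1, 1] to absorb last-ulp excursions.

An offset is marked when the max-over-library score **strictly** exceeds the
threshold (a tie is not a detection). Marked offsets are grouped into
clusters — one cluster, one counted cell:

- without a skip pattern, clusters are 8-connected components
  (`scipy.ndimage.label`);
- with a pattern, surviving marks of one cell can be further apart, so the
  merge radius widens to the Chebyshev distance
  `max(max(m,n) − 1, pattern lattice gap)`, where (m, n) is the expected
  cluster extent (default 3×3) and the lattice gap is the largest cyclic
  spacing between evaluated rows/columns of the mask. Without the second
  term a stride-3 mask would split one cell's survivors (3 apart) into
  several counts and sparse counting could exceed dense counting, which is
  physically wrong. Radius-r clustering uses a KD-tree plus union-find,
  since ndimage structuring elements cap at 3×3.

Clusters wider than the nominal m×n are counted once, not split: the cap is
a physical expectation about cell footprints, not a segmentation rule. The
number of oversized clusters is logged. At the default operating threshold
of 0.67 the synthetic scenes routinely produce clusters of extent 5–7,
because the NCC peak of a smooth blob is itself smooth; this is harmless for
counting as long as cells are separated by more than the cluster extent.

## Skip patterns

A pattern is a small boolean period mask tiled over the offset grid anchored
at (0, 0). The four presets are reconstructions: the published comparison
gives each pattern's runtime reduction and skipped-points-of-9 count but
shows the masks only as figures, and exactly one assignment of simple
periodic masks reproduces every (reduction, skipped) pair — alternate rows
(50%, 3), checkerboard (50%, 4), stride 2 in both axes (75%, 5), stride 3 in
both axes (89%, 8). The row-skipping vs checkerboard identification of the
first two rests on their different best-case skip counts; both halve the
work. Custom masks can be supplied as 0/1 text or JSON grids.

Runtime reduction is reported as `100·(1 − density)` with the density
computed exactly (rational arithmetic over one period) before rounding.
"Runtime" throughout the package means the deterministic NCC evaluation
count — evaluated offsets × library size — which is hardware-independent;
wall-clock is logged for information only.

The detection-probability model treats the `t = m·n` offsets of a cluster as
independent Bernoulli(`p_mark`) exceedances. Conditioning on the dense
detector having found the cell gives

    P = [1 − (1 − p_mark)^(t−s)] / [1 − (1 − p_mark)^t].

The numerator exponent is the number of **evaluated** points `t − s`. (The
alternative reading with exponent `s` fails to reproduce the published
per-pattern probabilities — it gives 87.7% instead of 98.6% for the
alternate-row pattern — so `t − s` is used.) `p_mark = 0.5` models the
critical region where scores hover at the threshold; that region dominates
the loss, since clusters far above threshold survive any pattern. The
skipped count `s` depends on how the cluster aligns with the period;
`skipped_in_cluster` reports both the best and worst case, and the preset
summary quotes the best case, as the published figures do. A seeded
Monte-Carlo validator (`simulate_detection`) checks the closed form.

## Library influence and pruning

Influence uses sequential first-detector attribution: templates are visited
in library order, each template's own detections are computed once, and a
cluster is credited to a template only if it does not overlap a cluster
already credited to an earlier one. Overlap is tested between the new
cluster's member offsets and the radius-dilated body of claimed clusters
(radius `max(m,n) − 1`). Testing against the cluster *body* rather than
centroid distance matters when real clusters exceed the nominal extent: two
templates seeing the same cell can centre their clusters more than
`max(m,n) − 1` apart, and centroid-distance bookkeeping then double-counts
the cell. An alternative arg-max-NCC attribution is available behind a flag
for sensitivity analysis.

Attribution is deliberately order-dependent: in a shuffled library an exact
duplicate that precedes its source becomes the scoring head and the source
scores zero. The invariant property is "at most one nonzero-influence member
per group of identical templates", which is what the tests assert.

Pruning first removes all zero-influence templates (projected lossless,
verified by recount), then greedily removes the lowest-influence remaining
template — recomputing influence after each removal, ties broken by library
order — while the recounted cumulative loss versus the full library stays
within the budget. Per-template surfaces are cached, so each recount is a
subset maximum rather than a recomputation. The pruner refuses to empty the
library. "Similarity" is never thresholded directly; redundancy is judged
purely by realized influence/loss, with `template_similarity` provided as a
diagnostic.

## Threshold model and compensation

Counts over the calibration band [0.60, 0.67] are fitted by ordinary least
squares on a threshold grid (default 8 points); the band's lower edge is the
weakest threshold still indicating strong correlation, and compensation
never goes below it. The compensation target is the un-optimized pipeline's
count at the operating threshold on the calibration samples. The inverted
threshold is clamped into [0.60, T_hi] with a flag when clamping occurs —
loss that would require a lower threshold is not compensable this way.

When counts are flat across the band the slope is zero and inversion is
undefined; `compensate_threshold` raises, and the `run_optimize` pipeline
treats this as "nothing to compensate" and keeps the operating threshold.
Flat counts are the expected regime on clean, well-separated scenes where
every cell scores far above 0.67.

## Synthetic scenes

The generator emulates lensless holographic acquisitions: each cell is a
radially symmetric shadow — a dark Gaussian core plus a brighter
diffraction-like ring — drawn from three morphology variants (core sigma
1.8/2.6/3.4 px, ring radius 4.6/6.0/7.4 px, depths 70/35 intensity units on
a background of 140), on a linear background plane with i.i.d. Gaussian
noise. Defaults: 300×400 image, 60 cells, Chebyshev separation ≥ 20,
noise sigma 3.0 — chosen so that a template cropped from one cell correlates
above 0.8 with every other cell of its variant, the condition for the
0.67-threshold detector to recover the planted count. All randomness flows
through one seeded generator; scenes are bit-reproducible.

Template libraries are derived the way manual libraries are built: crops
centred on true cells (17×17 by default), with configurable fractions of
exact duplicates and jittered (≤ 2 px offset) near-duplicates, shuffled
under the seed. Distinct crops are taken round-robin across the morphology
variants so every variant is represented — without this a random draw can
miss a variant and the planted count becomes unrecoverable for reasons
unrelated to the optimizations under study.

What the generator does **not** emulate: true in-line holography optics
(interference fringes, twin images), spatially correlated sensor noise,
overlapping or touching cells, debris, and focus drift. Passing tests
therefore demonstrate the correctness and internal consistency of the
algorithms under controlled conditions, not field accuracy on real
acquisitions; on real data the threshold, cluster extent, and noise margins
all need recalibration.

## Validation problem sizes

The end-to-end benchmark (`optimized_vs_original`, also what the acceptance
script runs) uses 10 seeded scenes at the default 300×400 / 60-cell
conditions with a 12-template library (4 distinct, 4 exact duplicates, 4
jittered), an 8.5% pruning budget, the alternate-row pattern, and
compensation targeting the original count. On these conditions the pruner
typically keeps 1–3 templates at zero realized loss, the threshold stays at
0.67 (flat-count regime), and the optimized detector reproduces the original
count exactly while performing ~8% of the NCC evaluations. Monte-Carlo
validation of the detection-probability model uses 2×10⁵ clusters per
preset and a 3-binomial-SE acceptance band.

## Known limitations

- Counting assumes cells are separated by more than the cluster extent;
  touching cells merge into one cluster and under-count.
- No sub-pixel localization, rotation/scale invariance, or morphology
  measurement; detection is strictly translational template matching.
- The linear count-vs-threshold model holds only locally; extrapolating the
  fit outside the calibration band is not meaningful and the inversion is
  clamped accordingly.
- Influence attribution depends on library order (by design); the provided
  arg-max mode exists to quantify that sensitivity.
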