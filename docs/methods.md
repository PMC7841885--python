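# Methods

## The segmentation model

The pipeline treats a nucleus as a *locally dark, compact* object: darker
than its surrounding cytoplasm, convex, and not elongated. Four stages
operate on an 8-bit grayscale image (the green channel of RGB input,
which carries the most nuclear contrast in Papanicolaou-stained
material):

1. **Smoothing + adaptive threshold.** The image is smoothed with a
   separable Gaussian (kernel side `blur_kernel`, default 5; sigma
   `0.3·((k−1)/2 − 1) + 0.8`, the standard size-derived choice). Pixel
   *p* becomes foreground iff `I(p) < mean_w(p) − C` where `mean_w` is
   the arithmetic mean over the `wsize × wsize` window centred on *p*
   with edge-repeating reflect padding. The comparison is carried out in
   exact integer arithmetic (`I·w² < S − C·w²` with `S` the integer
   window sum), so the strict inequality has no floating-point ambiguity
   and the stage is verifiable against a per-pixel summation oracle. A
   Gaussian-weighted mean is available via `mean_type="gaussian"`.
2. **Kirsch edge subtraction.** The eight compass kernels (a row of three
   +5 coefficients rotated through eight orientations, −3 elsewhere, zero
   centre) are convolved with the blurred image; negative responses are
   clamped at zero before the per-pixel maximum is taken, giving a
   non-negative gradient that is exactly zero on constant regions.
   Pixels with gradient ≥ `kirsch_edge_threshold` (default 255) form an
   edge map that is set-subtracted from the foreground. The default
   threshold sits far above the noise floor (for noise sd 5 the flat-field
   response is ~55) yet far below a genuine step response (a contrast of
   Δ yields up to 15·Δ at the step), so only real boundaries are cut.
3. **Contour filtering.** Candidates are the 8-connected components of
   the cleaned mask, labelled in raster order of their first pixel, with
   holes filled (fill pixels are only claimed if globally background, so
   a component nested inside another's hole keeps its own pixels and
   regions stay disjoint). Features per region:
   - *size* — by default the outer-boundary pixel count (pixels with an
     8-neighbour outside the region); the filled area is available via
     `size_measure="area"`. The boundary convention is consistent with
     the published size bounds (e.g. 20–140 for nuclei tens of pixels
     across).
   - *solidity* — filled pixel count divided by the number of pixel
     centres inside-or-on the convex hull of the region's pixels.
     Counting hull pixels (rather than the hull polygon's shoelace area)
     makes a filled rectangle's solidity exactly 1 and bounds the ratio
     by 1; degenerate regions (single pixel, collinear) get solidity 1 by
     convention.
   - *inertia ratio* — `sqrt(λ_min/λ_max)` of the 2×2 second-central-
     moment matrix of the pixel coordinates: the minor/major axis ratio
     of the equivalent ellipse. Fewer than two pixels → 1 by convention.
   A region is kept iff `MinSize ≤ size ≤ MaxSize`, `solidity ≥
   MinSolid` and `inertia_ratio ≥ MinInertia`.
4. **Recovery.** Edge subtraction shrinks true nuclei, so each survivor
   is re-grown on the **raw** (unblurred) grayscale image — the admission
   criterion describes true nucleus darkness, not the smoothed signal. A
   FIFO queue is seeded with the region's boundary pixels in raster
   order; an 8-neighbour is admitted when its intensity is within
   `Irange` of the region's running mean, which is updated after every
   admission. After each admission the stopping conditions are checked:
   size > `MaxSize` or solidity < `recovery_solidity` (0.75, slightly
   below the ~0.8 solidity of a valid nucleus) halt growth immediately
   with no rollback; exhaustion of the queue is the natural stop.
   Termination is guaranteed because each admission strictly enlarges the
   region within a finite image. Pixels owned by another region are never
   admitted; regions grow in label order, so contested pixels go to the
   first claimer and the output is deterministic. The grown-region
   solidity is maintained incrementally: the convex hull is only
   recomputed when an admitted pixel falls outside the current hull
   (an interior admission can only raise solidity), which keeps the
   per-admission cost low without changing the result.

## Tunable parameters

| name | meaning | unit | default |
|---|---|---|---|
| `wsize` | adaptive-threshold window side | px (odd) | 35 |
| `C` | threshold offset below local mean | intensity | 50 |
| `Irange` | admissible deviation from region mean during recovery | intensity | 40 |
| `MinSolid` | minimum solidity | – | 0.8 |
| `MinSize` / `MaxSize` | contour-size window | px | 5 / 50 |
| `MinInertia` | minimum axis ratio | – | 0.3 |
| `recovery_solidity` | fixed growth-stop solidity | – | 0.75 |
| `dice_threshold` | fixed TP gate | – | 0.6 |
| `kirsch_edge_threshold` | edge-map cut-off | gradient | 255 |
| `blur_kernel` | Gaussian kernel side | px (odd) | 5 |

Larger `wsize` suits images whose nuclei are more zoomed in; larger `C`
suits lower nucleus/background contrast; larger `Irange` suits higher
nucleus/cytoplasm contrast. `ISBI_PARAMS` and `BSMMU_CASE1..3` expose the
published parameter rows. Defaults are the Case-1 row.

## Evaluation protocol

Per-image instance matching is greedy one-to-one by descending pairwise
Dice among overlapping (ground-truth, prediction) pairs, ties broken by
(gt label, pred label); the protocol itself does not fix a many-to-many
resolution, and greedy descending-Dice is the deterministic standard
choice. A matched pair with Dice ≥ 0.6 is a TP; every other prediction is
an FP and every unmatched ground-truth nucleus an FN, so TP+FN = #gt and
TP+FP = #pred by construction. AJI matches each ground-truth instance to
the unused prediction with maximal Jaccard overlap (ties to the lowest
label), accumulating intersections over unions and adding unmatched
prediction pixels to the denominator. Image sets are pooled by summing
TP/FP/FN (and the AJI numerator/denominator terms) across images —
micro-averaging — with per-image values also reported, since the
aggregation convention is not fixed by the protocol.

## Tuning

`grid_search` enumerates the Cartesian product of per-parameter candidate
lists in a fixed key order, scores each combination by pooled metric over
the training pairs, and returns the first argmax plus the full audit
table. `default_grid()` brackets the published parameter rows
(972 combinations); `synthetic_study_grid()` is the compact
16-combination grid of published values used by the desk-scale synthetic
study. No validation split is used (a warning is logged): with ~10
training images the selected values can overfit.

## Synthetic fixtures

The generator emulates the qualitative structure of a smear field of
view: 256×256 pixels (half the linear size of the public challenge
images, nucleus semi-axes 5–12 px scaled accordingly), 2–10 cells, each a
rotated filled ellipse of uniform intensity 40–80 inside a concentric
cytoplasm ellipse of 140–180 on a 230 background, Gaussian noise sd 5,
plus distractors drawn in the nucleus intensity band so that only shape
can reject them: 2-px-thick bars (inertia ratio < 0.2), crescents
(solidity < 0.6) and 1–2-px speckles. Nuclei are placed without overlap
and with a 3-px separation margin; placement failure after 200 attempts
raises. All randomness flows from one `numpy` generator keyed by the
seed.

What the fixtures deliberately do **not** model: overlapping cytoplasm
and nuclei, intensity gradients within a nucleus, chromatin texture,
out-of-focus blur, and staining variability. Passing the synthetic
end-to-end study therefore demonstrates the pipeline's internal
consistency — each stage does what it claims on images satisfying its
assumptions — not clinical-grade performance on real slides, which is
why the published parameter rows and the tuner exist.

## Numerical choices and degenerate inputs

- All mask logic is boolean; thresholding is integer-exact (see above).
- Reflect padding everywhere is the edge-repeating (`symmetric`) variant
  used by `scipy.ndimage`.
- Hull membership uses half-plane tests with a 1e-9 tolerance so pixels
  exactly on a hull facet count as inside.
- `prf1` returns NaN for undefined counts (e.g. TP+FP = 0); `aji` and
  `dice` raise on empty ground truth / two empty sets.
- Region labels, queue orders and tie-breaks are all raster- or
  label-ordered, making every pipeline output bit-reproducible.
- Growth with `Irange = 0` on a region whose boundary meets only
  differing intensities is a fixed point.

## Problem sizes in the shipped study

The acceptance study tunes on 10 generated fixtures and evaluates on 20
held-out fixtures of 256×256 px with the 16-combination grid — about
160 pipeline runs for tuning plus 20 for evaluation, a few minutes on one
CPU. These sizes are the package's desk-scale study conditions; larger
grids (e.g. `default_grid()`) and image counts scale linearly.

## Known limitations

- Merged or overlapping nuclei are not split (no watershed-style
  separation); the recovery stage assigns contested pixels to the first
  claimer.
- When the adaptive-threshold window is large relative to a cell, an
  entire cell (cytoplasm + nucleus) can binarise as one blob whose
  shape passes the filter; a smaller `wsize` is the remedy, which is
  precisely what the tuner selects on zoomed-out material.
- The boundary-vs-area reading of "contour size" is exposed as
  configuration because either convention is defensible; the tuner can
  operate under both.
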