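# Methods

This note documents the models and procedures implemented in
`occubalance`, the parameters that matter, the choices made where the
design was open, and what the synthetic test fixtures do and do not
demonstrate.

## Counting and planning

A detection dataset is partitioned into sub-datasets by (region,
illumination); each sub-dataset crossed with the eight occlusion classes
{N, L, F, B, LF, BL, BF, BLF} gives the *cells* of a count table.  The
balance plan raises every cell of every retained sub-dataset to a common
target:

* **Skip rule.** A sub-dataset whose total box count falls below
  `min_boxes_to_retain` (default **1000**) is excluded from balancing.
  Oversampling a slice with a few hundred boxes would replicate a
  handful of source fruits thousands of times, which defeats the purpose
  of diversity-preserving augmentation.  On the published MTOA count
  table this default separates the two near-empty slices (491 and 0
  boxes) from the retained four (8,159–36,803 boxes).
* **Target.** The maximum cell count over retained sub-datasets, i.e.
  the largest class anywhere survives untouched and everything else is
  raised to it.  An explicit `--target` override exists for scaled-down
  runs.
* **Deficit.** `target − count` per retained cell, by construction
  non-negative; the defining invariant `count + deficit == target` is
  asserted property-style over random tables in the test suite.
* **Shares and ratios.** Percentage shares are rounded half-up to one
  decimal; imbalance ratios are carried as exact rationals plus their
  integer floors (the convention for quoting "~16×" differences).

## Illumination

The binary high/low illumination label is an injection point.  The
default labeler thresholds the mean Rec.601 luma (0.299 R + 0.587 G +
0.114 B) at **90/255**: it is deterministic, monotone in brightness, and
sufficient to drive the pipeline's key requirement — that synthesis
never mixes high- and low-illumination stock.  It is *not* claimed to
reproduce the assignments of a trained scene classifier (backlight and
color-distorted artificial lighting are not simple luminance phenomena);
a trained model can be passed as `predictor`, and records carrying an
illumination tag in the manifest bypass classification entirely.

## Synthesis geometry

All synthesis pastes RGBA occlusion elements (alpha = segmentation mask,
binarized at 128) onto an unoccluded substrate crop; the output always
has the substrate's size.

**Edge-entry rule (branch, leaf, composite).**  The substrate is gridded
6×6.  The occluder's start point is uniform over the 24 boundary lattice
points — occluders physically enter from outside the fruit.  The end
point must (a) share neither row nor column with the start, so the
spanned region is a proper rectangle, and (b) lie strictly more than 3
grid lengths away, so the occluder visibly crosses the crop.  "Grid
lengths" is interpreted as **Chebyshev distance** on the lattice, the
natural metric for an axis-aligned exclusion area; Euclidean is
available behind the `metric` flag.  The element is first cropped to a
scale-`s` sub-window (`s` uniform in [0.5, 1.0], window `s·w × s·h`
centered on the element's opacity centroid) and then resized
anisotropically into the start/end rectangle.  Sampling start/end at
lattice points (rather than continuous pixels) keeps placements aligned
with the stated 24-point entry area.

**Quadrant rule (fruit).**  A freely pasted fruit could bury the
substrate and invert which fruit the annotation describes.  Instead the
substrate (with its 6×6 grid) is centered on a canvas of 14×14 cells;
the occluding fruit is resized to the substrate size and its upper-left
corner is drawn uniformly at pixel resolution from the canvas's
upper-left 7×7-cell quadrant.  A draw is rejected until (a) the
footprint overlap with the substrate is at most **34%** of the substrate
area and (b) the fruit's centroid does not coincide with the canvas
origin (which would center it exactly on the substrate).  Rejection
sampling is used because unconstrained quadrant-1 corners can reach 100%
overlap (corner four cells in centers the fruit perfectly); the bound is
therefore a guarantee of the sampler, not of the quadrant geometry
alone.  The canvas is finally cropped back to the substrate footprint,
implemented as a clipped composite.  Acceptance probability under the
default geometry is high (≈35% of the quadrant area qualifies), so the
retry budget of 100 is never a practical limit.

**Fused classes.**  BL, BF, LF, BLF compose the single-element steps
sequentially — fruit first where present, so branch/leaf land on top —
or, alternatively, paste one pre-segmented composite element by the
edge-entry rule (`route="composite_element"`).  The emitted class label
is a pure function of the element kinds applied, which the tests assert
via provenance records.

**Substrates.**  N crops are cut from the sub-dataset's own images,
shuffled once (seeded) and cycled round-robin, so a deficit larger than
the available N population reuses substrates as evenly as possible.

**Blending** is hard alpha compositing with no feathering or photometric
harmonization; matching illumination between element and substrate is
handled by pool isolation, not color transfer.

## Component pool

Elements live under `{high,low}/{fruit,branch,leaf,composite}/*.png`
(RGBA), base images under `{high,low}/base/`.  Base images are resized
to one of two canonical sizes, 640×480 or 1280×720, chosen uniformly per
image; low-illumination base stock can be supplemented by Gaussian-blurred
variants (σ = 2.0, fraction configurable) — blur strength is a free
choice, set to a mild softening that leaves mean luminance unchanged.
Full-scale stocking levels (500 elements per class per illumination,
1000 base images) are validation *warnings*, not requirements, so toy
pools work.

## Packing and labels

Free space on a base image is managed as a shelf: crops go left to
right, a new row opens when the current one is full, a new base image
when the canvas is exhausted, with 5 px padding between crops and to the
borders.  This realizes a remaining-space contract deterministically and
makes each auto-label exactly the pasted rectangle — the pixel content
inside every annotation box equals the crop raster bit-for-bit, which
the tests check.  Crops are never resized during packing (labels must
match synthesis geometry); a crop that cannot fit any canonical base
errors out.  Crops of different classes may share a base image.

## Evaluation

Matching is greedy per class in descending confidence: a prediction
takes the unmatched same-class ground-truth box of highest IoU if that
IoU ≥ 0.5 (threshold configurable).  P = TP/(TP+FP), R = TP/(TP+FN),
with zero denominators defined as 0 and flagged rather than raising.
AP integrates the precision-recall curve by **all-point interpolation**
of the precision envelope (the 11-point variant is a flag); mAP is the
arithmetic mean of the eight per-class APs (factor 0.125).  Aggregate P
and R for a report are computed at a confidence cutoff (default 0.5),
since a threshold-free "the" precision of a detector is not well defined.

## Seeding

One master seed is fanned out per component via SHA-256-hashed names
into `numpy.random.SeedSequence`, so every stage is independently
reproducible and insensitive to other stages' draw counts.  All derived
seeds stay below 2³¹.  Two runs of the `balance` subcommand with equal
inputs and seed produce byte-identical output trees (PNG encoding
included), which the test suite verifies.

## Fixtures: what they show and what they do not

The fixture generator renders flat shapes — disk fruits, bar branches,
ellipse leaves — on noise backgrounds whose mean brightness encodes the
illumination label, with exactly the requested number of boxes per cell.
Shapes are rasterized as analytic point-set masks, so mask areas track
closed-form areas to rasterization error (≪1%).  This exercises every
counting, planning, geometric, packing and metric path of the pipeline,
and problem sizes in the tests are kept small (cells of ≤30 boxes,
target 30) so the full suite runs in seconds.  It does **not** emulate
real orchard statistics: no texture, no lighting gradients, no
photometric gap between synthetic and real crops.  Passing tests
demonstrate the correctness of the data arithmetic and geometry, not
that a detector trained on the synthetic output will improve — that
depends on element quality and domain match of the component pool.

## Known limitations

* Element segmentation is out of scope; pools are built from
  pre-segmented RGBA files (or fixtures).
* The luminance heuristic is a stand-in interface for a real
  illumination classifier.
* Shelf packing is deliberately not an optimal bin packer; it trades
  density for determinism and label cleanliness.
* No photometric blending; pasted edges are hard (an optional light
  feather is a natural extension point).
* Reported statistics are always computed from the data at hand;
  aggregate totals published elsewhere that disagree with their own
  per-cell tables are not "corrected" for.
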