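# occubalance

Balance augmentation for multi-type occlusion fruit-detection datasets.

## The problem

Detectors for orchard fruit picking must know not just *where* a fruit is
but *how it is hidden* — a branch in front of it calls for a different
grasp than an overlapping fruit.  Annotating apples with one of eight
occlusion classes — `N` (no occlusion), `L` (leaf), `F` (fruit), `B`
(branch) and the fused classes `LF`, `BL`, `BF`, `BLF` — produces
severely imbalanced training data: unoccluded apples dominate while
fully-occluded ones are rare, and the skew differs again across orchard
regions and between high- and low-illumination images.  In the public
MTOA orchard dataset the largest class holds ~28% of all boxes and the
smallest under 2%, and the largest-to-smallest nonzero cell ratio across
(region, illumination, class) cells is roughly 195:1.

`occubalance` equalizes those cells by *synthesizing* the missing
instances instead of cloning them:

1. **Count** annotation boxes per (region, illumination, class) cell.
2. **Plan** per-cell deficits toward a common target (the largest
   retained cell); slices with too few boxes overall are skipped.
3. **Synthesize** each missing instance by pasting segmented occlusion
   elements onto an unoccluded (`N`) crop under geometric rules — branch
   and leaf elements enter from the crop boundary on a 6×6 grid (start on
   one of the 24 boundary lattice points, end in a different row and
   column, more than three grid lengths away); an occluding fruit is
   placed on a 14×14-cell canvas with its corner in the upper-left
   quadrant and at most 34% footprint overlap with the substrate.
4. **Pack** the synthetic crops onto fruit-free base images with shelf
   layout, emitting exact bounding-box labels automatically.
5. **Evaluate** detections with PASCAL-VOC style P, R, per-class AP and
   the 8-class mAP = 0.125 · Σₙ AP(n).

Everything is driven by one master seed: identical inputs and seed give
byte-identical output trees.

## Worked example

Generate a toy dataset and component pool, count it, and balance it:

```
$ occubalance fixtures --out fx --regions ZY,QX --count-per-cell 5 --seed 0
fixture dataset and pool written under fx

$ occubalance stats --dataset fx/dataset --out counts.csv --min-boxes 10
{ "grand_total": 160, ... "class_ratio_floor": 1, ... }

$ occubalance balance --dataset fx/dataset --pool fx/pool \
      --out balanced --seed 0 --min-boxes 5 --target 9
target=9 synthesized=128 records=20
```

The last line says the plan raised every (region, illumination, class)
cell to 9 boxes, which required 128 synthetic instances, and the
balanced dataset holds 20 image records (the originals plus the packed
synthetic images, written under `balanced/` with VOC XML and YOLO txt
labels and a per-cell build manifest).

The planner can also run directly on a published count table.  With the
MTOA per-slice counts (shipped as a test asset):

```
$ occubalance plan --counts tests/data/mtoa_counts_by_illumination.csv --out plan.json
target=10579 retained=['PSR_H', 'QX_H', 'ZY_H', 'ZY_L']
```

i.e. the two low-count slices `QX_L` and `PSR_L` are skipped, every
retained cell is raised to 10,579 boxes (the largest retained cell), and
`plan.json` schedules 47,829 / 59,467 / 76,473 / 73,858 synthetic boxes
for `ZY_H` / `ZY_L` / `QX_H` / `PSR_H` respectively.

Library use mirrors the CLI: see `occubalance.balance_plan`
(`count_boxes`, `make_balance_plan`), `occubalance.synthesis`
(placement rules), `occubalance.packing` (`build_balanced_dataset`) and
`occubalance.metrics` (`evaluate`).

## Documentation

`docs/methods.md` describes the synthesis geometry, the planning
arithmetic, the illumination heuristic, all tunable parameters and the
known limitations.
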