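"""Procedural toy datasets, component pools and detections for testing.

The pipeline's logic is geometric and count-based — it never inspects
what a fruit looks like — so fixtures draw flat shapes: a filled disk is
a fruit, an elongated rectangle a branch, an ellipse a leaf.  Each
occlusion class is rendered with exactly the occluders its label names,
images carry a region tag and a controlled mean brightness per
illumination, and every requested (sub-dataset, class) cell receives
exactly the requested number of annotation boxes.  Shapes are rasterized
as analytic boolean masks (points inside the disk/ellipse inequality),
so mask areas track the closed-form areas to rasterization accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from occubalance._seeding import derive_rng
from occubalance.component_pool import (
    CANONICAL_BASE_SIZES,
    BaseImage,
    ComponentPool,
    Element,
    ElementKind,
)
from occubalance.dataset_io import (
    CLASS_ORDER,
    Annotation,
    BBox,
    Dataset,
    IlluminationLabel,
    ImageRecord,
    OcclusionClass,
    SubDatasetKey,
    write_manifest,
    write_voc,
)
from occubalance.errors import FixtureError
from occubalance.metrics import Detection

DEFAULT_ILLUMINATION_LEVELS = {
    IlluminationLabel.HIGH: 170.0,
    IlluminationLabel.LOW: 40.0,
}

# flat colors for the toy shapes (R, G, B)
_FRUIT_COLOR = np.array([200, 60, 50], dtype=np.uint8)
_BRANCH_COLOR = np.array([110, 80, 40], dtype=np.uint8)
_LEAF_COLOR = np.array([60, 140, 60], dtype=np.uint8)


@dataclass
class FixtureSpec:
    """What to generate: regions, per-cell box counts, rendering knobs."""

    regions: list[str] = field(default_factory=lambda: ["AA", "BB"])
    per_cell_counts: dict[tuple[SubDatasetKey, OcclusionClass], int] = field(
        default_factory=dict
    )
    image_size: tuple[int, int] = (192, 144)  # (width, height)
    box_slot: int = 48  # pixel pitch of the annotation slots
    seed: int = 0
    illumination_levels: dict[IlluminationLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_ILLUMINATION_LEVELS)
    )

    def __post_init__(self) -> None:
        for cell, v in self.per_cell_counts.items():
            if v < 0:
                raise FixtureError(f"negative count at {cell}")
        if self.box_slot > min(self.image_size):
            raise FixtureError("box_slot exceeds the image size: no box can fit")

    @classmethod
    def uniform(
        cls,
        regions: list[str],
        count_per_cell: int,
        illuminations: tuple[IlluminationLabel, ...] = tuple(IlluminationLabel),
        **kwargs,
    ) -> "FixtureSpec":
        counts = {
            (SubDatasetKey(region, ill), c): count_per_cell
            for region in regions
            for ill in illuminations
            for c in CLASS_ORDER
        }
        return cls(regions=regions, per_cell_counts=counts, **kwargs)

    @property
    def keys(self) -> list[SubDatasetKey]:
        return sorted({k for k, _ in self.per_cell_counts})


def _disk_mask(h: int, w: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def _ellipse_mask(h: int, w: int, cx: float, cy: float, a: float, b: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 / a**2 + (yy - cy) ** 2 / b**2 <= 1.0


def _paint(img: np.ndarray, mask: np.ndarray, color: np.ndarray) -> None:
    img[mask] = color


def _noise_background(
    h: int, w: int, level: float, rng: np.random.Generator
) -> np.ndarray:
    base = rng.integers(-12, 13, size=(h, w, 1))
    return np.clip(level + base, 0, 255).astype(np.uint8).repeat(3, axis=2)


def _draw_instance(
    img: np.ndarray, x0: int, y0: int, slot: int, cls: OcclusionClass,
    rng: np.random.Generator,
) -> BBox:
    """Draw one occlusion instance inside a slot; return its box."""
    h, w = img.shape[:2]
    margin = max(2, slot // 12)
    box = BBox(x0 + margin, y0 + margin, x0 + slot - margin, y0 + slot - margin)
    cx = (box.x_min + box.x_max) / 2 + rng.uniform(-2, 2)
    cy = (box.y_min + box.y_max) / 2 + rng.uniform(-2, 2)
    r = box.width * 0.32
    _paint(img, _disk_mask(h, w, cx, cy, r), _FRUIT_COLOR)
    comps = cls.components
    if "fruit" in comps:
        _paint(
            img,
            _disk_mask(h, w, cx - r * 0.9, cy - r * 0.9, r * 0.8)
            & _disk_mask(h, w, cx, cy, r * 1.6),
            (_FRUIT_COLOR * 0.8).astype(np.uint8),
        )
    if "branch" in comps:
        bh = max(2, int(r * 0.3))
        yb = int(cy - bh / 2 + rng.integers(-2, 3))
        img[yb : yb + bh, box.x_min : box.x_max] = _BRANCH_COLOR
    if "leaf" in comps:
        _paint(
            img,
            _ellipse_mask(h, w, cx + r * 0.5, cy + r * 0.5, r * 0.8, r * 0.5),
            _LEAF_COLOR,
        )
    return box


def generate_fixture_dataset(
    spec: FixtureSpec, out_dir: Path | str | None = None
) -> Dataset:
    """Render a toy dataset realizing the spec's per-cell counts exactly.

    Images are tiled into ``box_slot``-pixel slots; each slot holds one
    annotated instance.  With ``out_dir``, PNGs, VOC XML and a manifest
    CSV are written; the returned records carry their rasters either way.
    """
    w, h = spec.image_size
    slots_x, slots_y = w // spec.box_slot, h // spec.box_slot
    per_image = slots_x * slots_y
    if per_image == 0:
        raise FixtureError("image too small for a single slot")
    records: list[ImageRecord] = []
    for key in spec.keys:
        rng = derive_rng(spec.seed, "fixture_dataset", key.name)
        level = spec.illumination_levels[key.illumination]
        queue: list[OcclusionClass] = []
        for c in CLASS_ORDER:
            queue.extend([c] * spec.per_cell_counts.get((key, c), 0))
        for img_idx, start in enumerate(range(0, len(queue), per_image)):
            chunk = queue[start : start + per_image]
            img = _noise_background(h, w, level, rng)
            annotations = []
            for slot_idx, cls in enumerate(chunk):
                sx = (slot_idx % slots_x) * spec.box_slot
                sy = (slot_idx // slots_x) * spec.box_slot
                annotations.append(
                    Annotation(_draw_instance(img, sx, sy, spec.box_slot, cls, rng), cls)
                )
            image_id = f"{key.name}_fix_{img_idx:04d}"
            records.append(
                ImageRecord(
                    image_id=image_id,
                    path=(Path(out_dir) / f"{image_id}.png") if out_dir else None,
                    width=w,
                    height=h,
                    region=key.region,
                    annotations=annotations,
                    illumination=key.illumination,
                    raster=img,
                )
            )
    dataset = Dataset(records=records, name="fixture")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for record in records:
            Image.fromarray(record.raster).save(out_dir / f"{record.image_id}.png")
        write_voc(dataset, out_dir / "voc")
        write_manifest(dataset, out_dir / "manifest.csv")
    return dataset


def generate_fixture_pool(
    spec: FixtureSpec,
    out_dir: Path | str | None = None,
    elements_per_kind: int = 3,
    base_images_per_illumination: int = 2,
    element_size: int = 48,
) -> ComponentPool:
    """Procedural component pool: disk fruits, bar branches, ellipse
    leaves, union composites; base images at the canonical sizes with the
    per-illumination mean brightness.  With ``out_dir``, the standard
    pool directory layout is written."""
    elements: dict[tuple[ElementKind, IlluminationLabel], list[Element]] = {}
    base_images: dict[IlluminationLabel, list[BaseImage]] = {}
    s = element_size
    for ill in IlluminationLabel:
        dim = 1.0 if ill is IlluminationLabel.HIGH else 0.45
        rng = derive_rng(spec.seed, "fixture_pool", ill.value)
        for kind in ElementKind:
            items = []
            for i in range(elements_per_kind):
                rgba = np.zeros((s, s, 4), dtype=np.uint8)
                rgb = rgba[:, :, :3]
                alpha = np.zeros((s, s), dtype=bool)
                r = s * (0.30 + 0.04 * i)
                if kind in (ElementKind.FRUIT, ElementKind.COMPOSITE):
                    m = _disk_mask(s, s, s / 2, s / 2, r)
                    rgb[m] = (_FRUIT_COLOR * dim).astype(np.uint8)
                    alpha |= m
                if kind in (ElementKind.BRANCH, ElementKind.COMPOSITE):
                    bh = max(3, int(s * 0.14))
                    y0 = s // 2 - bh // 2
                    rgb[y0 : y0 + bh, :] = (_BRANCH_COLOR * dim).astype(np.uint8)
                    m = np.zeros((s, s), dtype=bool)
                    m[y0 : y0 + bh, :] = True
                    alpha |= m
                if kind in (ElementKind.LEAF, ElementKind.COMPOSITE):
                    m = _ellipse_mask(s, s, s / 2, s / 2, r, r * 0.55)
                    rgb[m] = (_LEAF_COLOR * dim).astype(np.uint8)
                    alpha |= m
                rgba[:, :, 3] = np.where(alpha, 255, 0)
                items.append(
                    Element(
                        kind=kind,
                        illumination=ill,
                        raster=rgba,
                        source_id=f"{ill.value}_{kind.value}_{i:02d}",
                    )
                )
            elements[(kind, ill)] = items
        level = spec.illumination_levels[ill]
        bases = []
        for i in range(base_images_per_illumination):
            bw, bh = CANONICAL_BASE_SIZES[i % len(CANONICAL_BASE_SIZES)]
            bases.append(
                BaseImage(
                    raster=_noise_background(bh, bw, level, rng),
                    illumination=ill,
                    source_id=f"{ill.value}_base_{i:02d}",
                )
            )
        base_images[ill] = bases
    pool = ComponentPool(elements=elements, base_images=base_images)
    if out_dir is not None:
        out_dir = Path(out_dir)
        for (kind, ill), items in pool.elements.items():
            d = out_dir / ill.value / kind.value
            d.mkdir(parents=True, exist_ok=True)
            for el in items:
                Image.fromarray(el.raster, mode="RGBA").save(d / f"{el.source_id}.png")
        for ill, bases in pool.base_images.items():
            d = out_dir / ill.value / "base"
            d.mkdir(parents=True, exist_ok=True)
            for b in bases:
                Image.fromarray(b.raster).save(d / f"{b.source_id}.png")
    return pool


def generate_fixture_predictions(
    dataset: Dataset, quality: float, rng: np.random.Generator
) -> list[Detection]:
    """Detections whose fidelity degrades smoothly with ``quality``.

    quality 1 reproduces every ground-truth box at confidence 1; lower
    quality drops boxes, jitters survivors and injects random false
    positives, so expected AP rises monotonically with quality.
    """
    if not (0.0 <= quality <= 1.0):
        raise ValueError("quality must be in [0, 1]")
    preds: list[Detection] = []
    for record in dataset:
        n_gt = len(record.annotations)
        for ann in record.annotations:
            if quality >= 1.0:
                preds.append(Detection(record.image_id, ann.box, ann.cls, 1.0))
                continue
            if rng.random() >= quality:
                continue  # missed detection
            amp = (1.0 - quality) * 0.25
            b = ann.box
            jx = int(rng.normal(0, amp * b.width))
            jy = int(rng.normal(0, amp * b.height))
            box = BBox(
                max(0, b.x_min + jx),
                max(0, b.y_min + jy),
                min(record.width, max(b.x_min + jx + 2, b.x_max + jx)),
                min(record.height, max(b.y_min + jy + 2, b.y_max + jy)),
            )
            conf = float(np.clip(rng.normal(quality, 0.08), 0.05, 1.0))
            preds.append(Detection(record.image_id, box, ann.cls, conf))
        if quality < 1.0:
            n_fp = int(round((1.0 - quality) * max(n_gt, 1) * 0.5))
            for _ in range(n_fp):
                bw = int(rng.integers(8, max(9, record.width // 3)))
                bh = int(rng.integers(8, max(9, record.height // 3)))
                x0 = int(rng.integers(0, max(1, record.width - bw)))
                y0 = int(rng.integers(0, max(1, record.height - bh)))
                cls = CLASS_ORDER[int(rng.integers(len(CLASS_ORDER)))]
                conf = float(np.clip(rng.uniform(0.05, 0.6 + 0.4 * (1 - quality)), 0.0, 1.0))
                preds.append(
                    Detection(record.image_id, BBox(x0, y0, x0 + bw, y0 + bh), cls, conf)
                )
    return preds
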