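"""Packing synthetic crops onto base images and building the balanced set.

Synthetic crops are laid out on fruit-free base images with a shelf
policy — left to right along a row, a new row when the current one is
full, a fresh base image when the canvas is exhausted — which keeps
placements disjoint and makes every auto-generated label exactly the
pasted extent.  The balanced dataset is the basic training set plus the
packed synthetic images, with every retained (sub-dataset, class) cell
raised to the plan target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from PIL import Image

from occubalance._seeding import derive_rng
from occubalance.balance_plan import BalancePlan
from occubalance.component_pool import (
    CANONICAL_BASE_SIZES,
    BaseImage,
    ComponentPool,
    ElementKind,
    sample_base_image,
    sample_element,
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
    write_voc,
    write_yolo,
)
from occubalance.errors import PackingError
from occubalance.synthesis import (
    Provenance,
    SyntheticCrop,
    extract_n_crops,
    synthesize_fruit_occlusion,
    synthesize_fused,
    synthesize_single_occluder,
)

DEFAULT_PADDING = 5


@dataclass
class PackedImage:
    """One rendered base image bearing pasted crops and their labels."""

    raster: np.ndarray
    annotations: list[Annotation]
    key: SubDatasetKey | None = None
    provenance: list[Provenance] = field(default_factory=list)


class _Canvas:
    """Shelf-packing state over one base image."""

    def __init__(self, base: BaseImage, padding: int) -> None:
        self.base = base
        self.padding = padding
        self.width, self.height = base.size
        self.cursor_x = padding
        self.cursor_y = padding
        self.row_height = 0
        self.placements: list[tuple[SyntheticCrop, BBox]] = []

    def try_place(self, crop: SyntheticCrop) -> BBox | None:
        w, h = crop.size
        pad = self.padding
        x, y = self.cursor_x, self.cursor_y
        if x + w > self.width - pad:  # row full: open a new shelf
            x = pad
            y = self.cursor_y + self.row_height + pad
        if x + w > self.width - pad or y + h > self.height - pad:
            return None
        if y != self.cursor_y:
            self.cursor_y = y
            self.row_height = 0
        box = BBox(x, y, x + w, y + h)
        self.placements.append((crop, box))
        self.cursor_x = x + w + pad
        self.row_height = max(self.row_height, h)
        return box

    def render(self, key: SubDatasetKey | None) -> PackedImage:
        raster = self.base.raster.copy()
        annotations = []
        provenance = []
        for crop, box in self.placements:
            raster[box.y_min : box.y_max, box.x_min : box.x_max] = crop.raster
            annotations.append(Annotation(box, crop.cls))
            provenance.append(crop.provenance)
        return PackedImage(raster=raster, annotations=annotations, key=key, provenance=provenance)


def pack_crops(
    crops: Sequence[SyntheticCrop],
    base_supplier: Callable[[np.random.Generator], BaseImage],
    rng: np.random.Generator,
    padding: int = DEFAULT_PADDING,
    key: SubDatasetKey | None = None,
) -> list[PackedImage]:
    """Place every crop exactly once onto shelf-packed base images.

    ``base_supplier`` is called (with the rng) whenever a fresh base
    image is needed.  A crop that cannot fit even on an empty canonical
    base raises :class:`PackingError`.
    """
    max_w = max(w for w, _ in CANONICAL_BASE_SIZES)
    max_h = max(h for _, h in CANONICAL_BASE_SIZES)
    for i, crop in enumerate(crops):
        w, h = crop.size
        if w + 2 * padding > max_w or h + 2 * padding > max_h:
            raise PackingError(
                f"crop #{i} ({crop.cls.code}, {w}x{h}) exceeds every base size"
            )
    packed: list[PackedImage] = []
    canvas: _Canvas | None = None
    for i, crop in enumerate(crops):
        placed = canvas.try_place(crop) is not None if canvas else False
        attempts = 0
        while not placed:
            if canvas is not None and canvas.placements:
                packed.append(canvas.render(key))
            canvas = _Canvas(base_supplier(rng), padding)
            placed = canvas.try_place(crop) is not None
            attempts += 1
            if not placed and attempts >= 10:
                w, h = crop.size
                raise PackingError(
                    f"crop #{i} ({crop.cls.code}, {w}x{h}) does not fit on the "
                    f"supplied base images"
                )
    if canvas is not None and canvas.placements:
        packed.append(canvas.render(key))
    return packed


def _synthesize_cell(
    basic_train: Dataset,
    key: SubDatasetKey,
    cls: OcclusionClass,
    count: int,
    pool: ComponentPool,
    rng: np.random.Generator,
    route: str,
) -> list[SyntheticCrop]:
    substrates = extract_n_crops(basic_train, key, count, rng, with_source_ids=True)
    crops: list[SyntheticCrop] = []
    for raster, image_id in substrates:
        if cls is OcclusionClass.N:
            crops.append(
                SyntheticCrop(
                    raster=raster.copy(),
                    cls=OcclusionClass.N,
                    provenance=Provenance(source_image_id=image_id),
                )
            )
        elif cls in (OcclusionClass.B, OcclusionClass.L):
            kind = ElementKind.BRANCH if cls is OcclusionClass.B else ElementKind.LEAF
            element = sample_element(pool, kind, key.illumination, rng)
            crops.append(
                synthesize_single_occluder(
                    raster, element, rng, source_image_id=image_id
                )
            )
        elif cls is OcclusionClass.F:
            fruit = sample_element(pool, ElementKind.FRUIT, key.illumination, rng)
            crops.append(
                synthesize_fruit_occlusion(raster, fruit, rng, source_image_id=image_id)
            )
        else:
            crops.append(
                synthesize_fused(
                    raster, cls, pool, key.illumination, rng,
                    route=route, source_image_id=image_id,
                )
            )
    return crops


def build_balanced_dataset(
    basic_train: Dataset,
    plan: BalancePlan,
    pool: ComponentPool,
    seed: int,
    out_dir: Path | str | None = None,
    padding: int = DEFAULT_PADDING,
    route: str = "sequential",
) -> tuple[Dataset, dict]:
    """Synthesize every planned deficit, pack, label, and merge.

    Returns the balanced dataset (basic training records plus packed
    synthetic records) and a build manifest of scheduled vs produced
    counts per cell.  With ``out_dir``, packed images are written as PNG
    with sidecar Pascal VOC XML and YOLO txt plus the manifest; nothing
    is written unless the whole build succeeds.
    """
    new_records: list[ImageRecord] = []
    manifest: dict = {"target": plan.target, "cells": [], "packed_images": {}}
    for key in sorted(plan.retained_keys):
        crops: list[SyntheticCrop] = []
        for cls in CLASS_ORDER:
            deficit = plan.deficit(key, cls)
            if deficit == 0:
                continue
            rng_cell = derive_rng(seed, "synthesis", key.name, cls.code)
            cell_crops = _synthesize_cell(
                basic_train, key, cls, deficit, pool, rng_cell, route
            )
            manifest["cells"].append(
                {
                    "key": key.name,
                    "cls": cls.code,
                    "scheduled": deficit,
                    "produced": len(cell_crops),
                }
            )
            crops.extend(cell_crops)
        if not crops:
            continue
        rng_pack = derive_rng(seed, "packing", key.name)
        packed = pack_crops(
            crops,
            lambda r, ill=key.illumination: sample_base_image(pool, ill, r),
            rng_pack,
            padding=padding,
            key=key,
        )
        manifest["packed_images"][key.name] = len(packed)
        suffix = "H" if key.illumination is IlluminationLabel.HIGH else "L"
        for i, pimg in enumerate(packed):
            image_id = f"{key.region}_{suffix}_syn_{i:05d}"
            h, w = pimg.raster.shape[:2]
            new_records.append(
                ImageRecord(
                    image_id=image_id,
                    path=(Path(out_dir) / f"{image_id}.png") if out_dir else None,
                    width=w,
                    height=h,
                    region=key.region,
                    annotations=pimg.annotations,
                    illumination=key.illumination,
                    raster=pimg.raster,
                )
            )
    balanced = Dataset(
        records=list(basic_train.records) + new_records,
        name=f"{basic_train.name}_balanced",
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        synthetic = Dataset(records=new_records, name="synthetic")
        for record in new_records:
            Image.fromarray(record.raster).save(out_dir / f"{record.image_id}.png")
        write_voc(synthetic, out_dir / "voc")
        write_yolo(synthetic, out_dir / "yolo")
        (out_dir / "build_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return balanced, manifest
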