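"""The component pool: occlusion elements and base images for synthesis.

The pool holds four kinds of occlusion element (fruit, branch, leaf,
composite) as RGBA rasters whose alpha channel is the paste mask, and
fruit-free base images, all indexed by illumination.  High- and
low-illumination stock never mix: a low-light synthetic fruit is built
only from low-light parts.  Directory layout::

    pool_dir/{high,low}/{fruit,branch,leaf,composite}/*.png
    pool_dir/{high,low}/base/*.{png,jpg}
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image, ImageFilter

from occubalance._seeding import derive_rng
from occubalance.dataset_io import IlluminationLabel
from occubalance.errors import PoolError, ValidationError

logger = logging.getLogger(__name__)

#: The two canonical base-image sizes, (width, height).
CANONICAL_BASE_SIZES: tuple[tuple[int, int], ...] = ((640, 480), (1280, 720))

#: Alpha values >= this count as opaque when binarizing element masks.
ALPHA_THRESHOLD = 128

#: Validation targets for a full-scale pool (warnings, not hard limits).
FULL_POOL_ELEMENTS_PER_CLASS = 500
FULL_POOL_BASE_IMAGES = 1000


class ElementKind(enum.Enum):
    """What an occlusion element depicts."""

    FRUIT = "fruit"
    BRANCH = "branch"
    LEAF = "leaf"
    COMPOSITE = "composite"


@dataclass
class Element:
    """One occlusion element: RGBA raster whose alpha is the paste mask."""

    kind: ElementKind
    illumination: IlluminationLabel
    raster: np.ndarray  # HxWx4 uint8
    source_id: str

    def __post_init__(self) -> None:
        if self.raster.ndim != 3 or self.raster.shape[2] != 4:
            raise ValidationError(f"{self.source_id}: element raster must be HxWx4 RGBA")
        if self.raster.shape[0] == 0 or self.raster.shape[1] == 0:
            raise ValidationError(f"{self.source_id}: empty raster")
        if not (self.raster[:, :, 3] >= ALPHA_THRESHOLD).any():
            raise ValidationError(f"{self.source_id}: element mask has no opaque pixel")

    @property
    def mask(self) -> np.ndarray:
        """Boolean opacity mask (alpha binarized)."""
        return self.raster[:, :, 3] >= ALPHA_THRESHOLD


@dataclass
class BaseImage:
    """A fruit-free background at one of the two canonical sizes."""

    raster: np.ndarray  # HxWx3 uint8
    illumination: IlluminationLabel
    blurred: bool = False
    source_id: str = ""

    def __post_init__(self) -> None:
        h, w = self.raster.shape[:2]
        if (w, h) not in CANONICAL_BASE_SIZES:
            raise ValidationError(
                f"{self.source_id}: base image is {w}x{h}, expected one of "
                f"{CANONICAL_BASE_SIZES} (width x height)"
            )

    @property
    def size(self) -> tuple[int, int]:
        h, w = self.raster.shape[:2]
        return (w, h)


@dataclass
class ComponentPool:
    """Immutable lookup of elements and base images by (kind, illumination)."""

    elements: dict[tuple[ElementKind, IlluminationLabel], list[Element]] = field(
        default_factory=dict
    )
    base_images: dict[IlluminationLabel, list[BaseImage]] = field(default_factory=dict)

    def element_list(
        self, kind: ElementKind, illumination: IlluminationLabel
    ) -> list[Element]:
        return self.elements.get((kind, illumination), [])

    def base_list(self, illumination: IlluminationLabel) -> list[BaseImage]:
        return self.base_images.get(illumination, [])

    def summary(self) -> dict:
        return {
            "elements": {
                f"{ill.value}/{kind.value}": len(self.element_list(kind, ill))
                for ill in IlluminationLabel
                for kind in ElementKind
            },
            "base_images": {
                ill.value: len(self.base_list(ill)) for ill in IlluminationLabel
            },
        }


def _load_rgba(path: Path, background_key: tuple[int, int, int] | None) -> np.ndarray:
    with Image.open(path) as im:
        if im.mode == "RGBA":
            return np.asarray(im)
        rgb = np.asarray(im.convert("RGB"))
    if background_key is None:
        raise PoolError(
            f"{path}: element has no alpha channel and no background key was given"
        )
    alpha = np.where(
        (rgb == np.asarray(background_key, dtype=np.uint8)).all(axis=2), 0, 255
    ).astype(np.uint8)
    return np.dstack([rgb, alpha])


def load_pool(
    pool_dir: Path | str,
    background_key: tuple[int, int, int] | None = None,
) -> ComponentPool:
    """Load a pool directory; empty categories warn, unreadable files raise."""
    pool_dir = Path(pool_dir)
    elements: dict[tuple[ElementKind, IlluminationLabel], list[Element]] = {}
    base_images: dict[IlluminationLabel, list[BaseImage]] = {}
    for ill in IlluminationLabel:
        for kind in ElementKind:
            cat_dir = pool_dir / ill.value / kind.value
            items: list[Element] = []
            for p in sorted(cat_dir.glob("*.png")) if cat_dir.is_dir() else []:
                try:
                    raster = _load_rgba(p, background_key)
                except PoolError:
                    raise
                except Exception as exc:  # unreadable file
                    raise PoolError(f"failed to read element {p}: {exc}") from exc
                items.append(
                    Element(kind=kind, illumination=ill, raster=raster, source_id=p.stem)
                )
            if not items:
                logger.warning("component pool: empty category %s/%s", ill.value, kind.value)
            elements[(kind, ill)] = items
        base_dir = pool_dir / ill.value / "base"
        bases: list[BaseImage] = []
        patterns = ("*.png", "*.jpg", "*.jpeg")
        paths = sorted(p for pat in patterns for p in base_dir.glob(pat)) if base_dir.is_dir() else []
        for p in paths:
            try:
                with Image.open(p) as im:
                    raster = np.asarray(im.convert("RGB"))
            except Exception as exc:
                raise PoolError(f"failed to read base image {p}: {exc}") from exc
            bases.append(BaseImage(raster=raster, illumination=ill, source_id=p.stem))
        if not bases:
            logger.warning("component pool: no base images for %s", ill.value)
        base_images[ill] = bases
    return ComponentPool(elements=elements, base_images=base_images)


def validate_pool(
    pool: ComponentPool,
    elements_per_class: int = FULL_POOL_ELEMENTS_PER_CLASS,
    base_per_illumination: int = FULL_POOL_BASE_IMAGES,
) -> list[str]:
    """Full-scale stocking check; returns warning strings (empty = clean)."""
    warnings: list[str] = []
    for ill in IlluminationLabel:
        for kind in ElementKind:
            n = len(pool.element_list(kind, ill))
            if n < elements_per_class:
                warnings.append(
                    f"{ill.value}/{kind.value}: {n} elements "
                    f"(full-scale target {elements_per_class})"
                )
        nb = len(pool.base_list(ill))
        if nb < base_per_illumination:
            warnings.append(
                f"{ill.value}/base: {nb} base images "
                f"(full-scale target {base_per_illumination})"
            )
    return warnings


def write_pool_summary(pool: ComponentPool, path: Path | str) -> None:
    obj = pool.summary()
    obj["warnings"] = validate_pool(pool)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def prepare_base_images(
    images: Sequence[np.ndarray],
    illumination: IlluminationLabel,
    seed: int,
    blur_fraction: float = 0.0,
    blur_sigma: float = 2.0,
) -> list[BaseImage]:
    """Scale raw backgrounds to the canonical sizes; optionally blur some.

    Each image is resized to 640x480 or 1280x720, chosen uniformly at
    random under ``seed``.  For low illumination, each output is
    Gaussian-blurred (sigma ``blur_sigma``) with probability
    ``blur_fraction`` and flagged, supplementing scarce low-light
    backgrounds with softened variants.
    """
    if not images:
        raise ValueError("images must be nonempty")
    rng = derive_rng(seed, "prepare_base_images", illumination.value)
    out: list[BaseImage] = []
    for i, arr in enumerate(images):
        w, h = CANONICAL_BASE_SIZES[int(rng.integers(len(CANONICAL_BASE_SIZES)))]
        im = Image.fromarray(np.asarray(arr, dtype=np.uint8)).convert("RGB")
        im = im.resize((w, h), Image.BILINEAR)
        blurred = False
        if illumination is IlluminationLabel.LOW and blur_fraction > 0:
            if rng.random() < blur_fraction:
                im = im.filter(ImageFilter.GaussianBlur(radius=blur_sigma))
                blurred = True
        out.append(
            BaseImage(
                raster=np.asarray(im),
                illumination=illumination,
                blurred=blurred,
                source_id=f"prepared_{i:04d}",
            )
        )
    return out


def sample_element(
    pool: ComponentPool,
    kind: ElementKind,
    illumination: IlluminationLabel,
    rng: np.random.Generator,
) -> Element:
    """Uniform seeded draw from one (kind, illumination) category."""
    items = pool.element_list(kind, illumination)
    if not items:
        raise PoolError(
            f"component pool exhausted: no {kind.value} elements for "
            f"{illumination.value} illumination"
        )
    return items[int(rng.integers(len(items)))]


def sample_base_image(
    pool: ComponentPool, illumination: IlluminationLabel, rng: np.random.Generator
) -> BaseImage:
    """Uniform seeded draw of a base image for one illumination."""
    items = pool.base_list(illumination)
    if not items:
        raise PoolError(f"component pool exhausted: no base images for {illumination.value}")
    return items[int(rng.integers(len(items)))]
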