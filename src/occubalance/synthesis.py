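"""Synthesis of occluded fruit crops from unoccluded crops and pool elements.

An unoccluded ("N") crop is the substrate.  Occluders are pasted onto it
by two geometric rules that encode how occlusion actually arises:

* **Edge-entry rule** (branch/leaf/composite).  The crop is divided into
  a 6x6 grid.  Branches and leaves grow in from outside the fruit, so
  the occluder's start point is drawn from the 24 boundary lattice
  points.  Its end point must lie in a different row and column (the
  spanned region must be a rectangle, not a line) and more than three
  grid lengths away (Chebyshev), so the occluder visibly crosses the
  crop.  The element is first cropped to a 0.5-1.0 scale sub-window and
  then resized into the start/end rectangle.

* **Quadrant rule** (fruit-on-fruit).  A second fruit pasted freely
  could bury the substrate, flipping which fruit is "the" annotation.
  Instead, the crop is centered on a 14x14-cell canvas (its own 6x6 grid
  in the middle), the occluding fruit is resized to the crop size, and
  its upper-left corner is drawn from the canvas's upper-left quadrant.
  Placements are rejected until the footprint overlap with the substrate
  is at most 34% of the crop area and the occluder's centroid misses the
  canvas origin, then the canvas is cropped back to the substrate
  footprint.

Fused classes (BL, BF, LF, BLF) compose these steps sequentially, or
paste a pre-segmented composite element by the edge-entry rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from PIL import Image

from occubalance.component_pool import (
    ALPHA_THRESHOLD,
    ComponentPool,
    Element,
    ElementKind,
    sample_element,
)
from occubalance.dataset_io import (
    Annotation,
    BBox,
    Dataset,
    IlluminationLabel,
    OcclusionClass,
    SubDatasetKey,
)
from occubalance.errors import SynthesisError

#: Grid resolution of the substrate crop.
DEFAULT_CELLS_PER_SIDE = 6

#: Minimum start-to-end Chebyshev separation, in grid lengths (strict).
DEFAULT_MIN_SEPARATION = 3

#: Maximum footprint overlap between an occluding fruit and the substrate.
DEFAULT_MAX_OVERLAP = 0.34

#: Element crop scale range for the edge-entry rule.
DEFAULT_SCALE_RANGE = (0.5, 1.0)

DEFAULT_MAX_RETRIES = 100


@dataclass(frozen=True)
class GridSpec:
    """A square lattice over a crop: ``cells_per_side`` cells per axis."""

    cells_per_side: int
    cell_w: float
    cell_h: float

    def __post_init__(self) -> None:
        if self.cells_per_side < 2:
            raise ValueError("cells_per_side must be >= 2")
        if self.cell_w <= 0 or self.cell_h <= 0:
            raise ValueError("cell size must be positive")

    @classmethod
    def for_crop(
        cls, width: int, height: int, cells_per_side: int = DEFAULT_CELLS_PER_SIDE
    ) -> "GridSpec":
        return cls(cells_per_side, width / cells_per_side, height / cells_per_side)

    @property
    def crop_width(self) -> int:
        return int(round(self.cells_per_side * self.cell_w))

    @property
    def crop_height(self) -> int:
        return int(round(self.cells_per_side * self.cell_h))

    def pixel(self, point: "LatticePoint") -> tuple[int, int]:
        """(x, y) pixel coordinates of a lattice point."""
        return (int(round(point.col * self.cell_w)), int(round(point.row * self.cell_h)))


@dataclass(frozen=True, order=True)
class LatticePoint:
    """(row, col) indices on the (cells_per_side + 1)^2 lattice."""

    row: int
    col: int


@dataclass(frozen=True)
class PlacementSample:
    """An accepted edge-entry placement: start, end, element scale, box."""

    start: LatticePoint
    end: LatticePoint
    scale: float
    paste_box: BBox


@dataclass(frozen=True)
class FruitPlacement:
    """An accepted quadrant-rule placement of an occluding fruit."""

    corner: tuple[int, int]  # upper-left pixel of the fruit on the canvas
    overlap_fraction: float


@dataclass
class Provenance:
    """Where a synthetic crop came from: substrate id, elements, kinds."""

    source_image_id: str | None = None
    element_source_ids: list[str] = field(default_factory=list)
    element_kinds: list[str] = field(default_factory=list)


@dataclass
class SyntheticCrop:
    """A synthesized occlusion instance, same size as its substrate crop."""

    raster: np.ndarray  # HxWx3 uint8
    cls: OcclusionClass
    provenance: Provenance = field(default_factory=Provenance)

    @property
    def size(self) -> tuple[int, int]:
        h, w = self.raster.shape[:2]
        return (w, h)


# ---------------------------------------------------------------------------
# Lattice geometry


def edge_entry_points(grid: GridSpec) -> list[LatticePoint]:
    """The boundary lattice points (row-major); 4n points for an n-cell grid."""
    n = grid.cells_per_side
    return [
        LatticePoint(r, c)
        for r in range(n + 1)
        for c in range(n + 1)
        if r in (0, n) or c in (0, n)
    ]


def valid_endpoints(
    start: LatticePoint,
    grid: GridSpec,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    metric: str = "chebyshev",
) -> set[LatticePoint]:
    """End points admissible for ``start`` under the edge-entry rule.

    A point qualifies if it shares neither row nor column with the start
    (the spanned region must be a proper rectangle) and lies strictly
    more than ``min_separation`` grid lengths away.
    """
    if metric not in ("chebyshev", "euclidean"):
        raise ValueError("metric must be 'chebyshev' or 'euclidean'")
    n = grid.cells_per_side
    out: set[LatticePoint] = set()
    for r in range(n + 1):
        for c in range(n + 1):
            if r == start.row or c == start.col:
                continue
            dr, dc = abs(r - start.row), abs(c - start.col)
            dist = max(dr, dc) if metric == "chebyshev" else (dr * dr + dc * dc) ** 0.5
            if dist > min_separation:
                out.add(LatticePoint(r, c))
    return out


def sample_edge_placement(
    grid: GridSpec,
    rng: np.random.Generator,
    scale_range: tuple[float, float] = DEFAULT_SCALE_RANGE,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    metric: str = "chebyshev",
    max_retries: int = DEFAULT_MAX_RETRIES,
) -> PlacementSample:
    """Draw an edge-entry placement: boundary start, admissible end, scale."""
    entries = edge_entry_points(grid)
    for _ in range(max_retries):
        start = entries[int(rng.integers(len(entries)))]
        ends = sorted(valid_endpoints(start, grid, min_separation, metric))
        if not ends:
            continue  # degenerate small grid: resample the start
        end = ends[int(rng.integers(len(ends)))]
        scale = float(rng.uniform(*scale_range))
        sx, sy = grid.pixel(start)
        ex, ey = grid.pixel(end)
        paste_box = BBox(min(sx, ex), min(sy, ey), max(sx, ex), max(sy, ey))
        return PlacementSample(start=start, end=end, scale=scale, paste_box=paste_box)
    raise SynthesisError(
        f"no admissible start/end pair on a {grid.cells_per_side}-cell grid "
        f"after {max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# Raster helpers


def _crop_element_at_scale(raster: np.ndarray, scale: float) -> np.ndarray:
    """Sub-window of an RGBA element covering scale^2 of its area, centered
    at the opacity centroid (clamped into bounds)."""
    h, w = raster.shape[:2]
    cw = max(1, int(round(scale * w)))
    ch = max(1, int(round(scale * h)))
    mask = raster[:, :, 3] >= ALPHA_THRESHOLD
    if mask.any():
        ys, xs = np.nonzero(mask)
        cx, cy = float(xs.mean()), float(ys.mean())
    else:
        cx, cy = w / 2, h / 2
    x0 = int(round(cx - cw / 2))
    y0 = int(round(cy - ch / 2))
    x0 = min(max(x0, 0), w - cw)
    y0 = min(max(y0, 0), h - ch)
    return raster[y0 : y0 + ch, x0 : x0 + cw]


def _resize_rgba(raster: np.ndarray, width: int, height: int) -> np.ndarray:
    im = Image.fromarray(raster, mode="RGBA").resize((width, height), Image.BILINEAR)
    out = np.asarray(im).copy()
    out[:, :, 3] = np.where(out[:, :, 3] >= ALPHA_THRESHOLD, 255, 0)
    return out


def _composite(dst: np.ndarray, src_rgba: np.ndarray, x: int, y: int) -> None:
    """Hard alpha-composite ``src_rgba`` onto RGB ``dst`` at (x, y), clipped."""
    dh, dw = dst.shape[:2]
    sh, sw = src_rgba.shape[:2]
    x0, y0 = max(x, 0), max(y, 0)
    x1, y1 = min(x + sw, dw), min(y + sh, dh)
    if x0 >= x1 or y0 >= y1:
        return
    sub = src_rgba[y0 - y : y1 - y, x0 - x : x1 - x]
    mask = sub[:, :, 3] >= ALPHA_THRESHOLD
    region = dst[y0:y1, x0:x1]
    region[mask] = sub[:, :, :3][mask]


def _paste_edge_entry(
    n_crop: np.ndarray,
    element: Element,
    rng: np.random.Generator,
    grid: GridSpec | None,
    scale_range: tuple[float, float],
    min_separation: int,
    metric: str,
    max_retries: int,
) -> tuple[np.ndarray, PlacementSample]:
    h, w = n_crop.shape[:2]
    if grid is None:
        grid = GridSpec.for_crop(w, h)
    placement = sample_edge_placement(
        grid, rng, scale_range, min_separation, metric, max_retries
    )
    piece = _crop_element_at_scale(element.raster, placement.scale)
    box = placement.paste_box
    piece = _resize_rgba(piece, box.width, box.height)
    out = n_crop.copy()
    _composite(out, piece, box.x_min, box.y_min)
    return out, placement


# ---------------------------------------------------------------------------
# Single-occluder synthesis (B / L)


def synthesize_single_occluder(
    n_crop: np.ndarray,
    element: Element,
    rng: np.random.Generator,
    grid: GridSpec | None = None,
    scale_range: tuple[float, float] = DEFAULT_SCALE_RANGE,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    metric: str = "chebyshev",
    max_retries: int = DEFAULT_MAX_RETRIES,
    source_image_id: str | None = None,
) -> SyntheticCrop:
    """Paste one branch or leaf element onto an N crop by the edge-entry
    rule; the emitted class is B for a branch element, L for a leaf."""
    if element.kind not in (ElementKind.BRANCH, ElementKind.LEAF):
        raise SynthesisError(
            f"single-occluder synthesis needs a branch or leaf element, "
            f"got {element.kind.value}"
        )
    out, _ = _paste_edge_entry(
        n_crop, element, rng, grid, scale_range, min_separation, metric, max_retries
    )
    cls = OcclusionClass.B if element.kind is ElementKind.BRANCH else OcclusionClass.L
    return SyntheticCrop(
        raster=out,
        cls=cls,
        provenance=Provenance(
            source_image_id=source_image_id,
            element_source_ids=[element.source_id],
            element_kinds=[element.kind.value],
        ),
    )


# ---------------------------------------------------------------------------
# Fruit-occlusion synthesis (F)


def _fruit_canvas_layout(grid: GridSpec) -> tuple[int, int, int, int]:
    """(n_x0, n_y0, quad_w, quad_h): substrate offset on the canvas and the
    pixel extent of the upper-left quadrant.

    The canvas spans ``2*cells + 2`` cells per axis with the substrate's
    own grid centered, so a 6-cell crop sits on a 14x14 canvas with its
    corner 4 cells in, and each quadrant spans 7 cells.
    """
    cells = grid.cells_per_side
    canvas_cells = 2 * cells + 2
    offset_cells = (canvas_cells - cells) // 2
    n_x0 = int(round(offset_cells * grid.cell_w))
    n_y0 = int(round(offset_cells * grid.cell_h))
    quad_w = int(round((canvas_cells // 2) * grid.cell_w))
    quad_h = int(round((canvas_cells // 2) * grid.cell_h))
    return n_x0, n_y0, quad_w, quad_h


def fruit_overlap_fraction(grid: GridSpec, corner: tuple[int, int]) -> float:
    """Footprint overlap between an occluding fruit (resized to the crop
    size, upper-left at ``corner`` in canvas pixels) and the substrate,
    as a fraction of the substrate area."""
    w, h = grid.crop_width, grid.crop_height
    n_x0, n_y0, _, _ = _fruit_canvas_layout(grid)
    x, y = corner
    iw = min(x + w, n_x0 + w) - max(x, n_x0)
    ih = min(y + h, n_y0 + h) - max(y, n_y0)
    return max(iw, 0) * max(ih, 0) / (w * h)


def sample_fruit_placement(
    grid: GridSpec,
    rng: np.random.Generator,
    max_overlap: float = DEFAULT_MAX_OVERLAP,
    max_retries: int = DEFAULT_MAX_RETRIES,
) -> FruitPlacement:
    """Rejection-sample a quadrant-1 corner for an occluding fruit.

    The corner is uniform at pixel resolution over the upper-left
    quadrant of the canvas.  A draw is accepted when the footprint
    overlap with the substrate is at most ``max_overlap`` of the
    substrate area and the fruit's centroid does not coincide with the
    canvas origin (which would center it exactly on the substrate).
    """
    if not (0 < max_overlap < 1):
        raise ValueError("max_overlap must be in (0, 1)")
    w, h = grid.crop_width, grid.crop_height
    n_x0, n_y0, quad_w, quad_h = _fruit_canvas_layout(grid)
    origin = (n_x0 + w / 2, n_y0 + h / 2)  # canvas center = substrate center
    for _ in range(max_retries):
        x = int(rng.integers(quad_w))
        y = int(rng.integers(quad_h))
        frac = fruit_overlap_fraction(grid, (x, y))
        if frac > max_overlap:
            continue
        centroid = (x + w / 2, y + h / 2)
        if abs(centroid[0] - origin[0]) < 0.5 and abs(centroid[1] - origin[1]) < 0.5:
            continue
        return FruitPlacement(corner=(x, y), overlap_fraction=frac)
    raise SynthesisError(
        f"no admissible fruit placement after {max_retries} attempts "
        f"(max_overlap={max_overlap})"
    )


def synthesize_fruit_occlusion(
    n_crop: np.ndarray,
    fruit: Element,
    rng: np.random.Generator,
    max_overlap: float = DEFAULT_MAX_OVERLAP,
    max_retries: int = DEFAULT_MAX_RETRIES,
    source_image_id: str | None = None,
) -> SyntheticCrop:
    """Paste an occluding fruit by the quadrant rule and crop back to the
    substrate footprint; output class F, output size = input size."""
    if fruit.kind is not ElementKind.FRUIT:
        raise SynthesisError(f"fruit synthesis needs a fruit element, got {fruit.kind.value}")
    h, w = n_crop.shape[:2]
    grid = GridSpec.for_crop(w, h)
    n_x0, n_y0, _, _ = _fruit_canvas_layout(grid)
    placement = sample_fruit_placement(grid, rng, max_overlap, max_retries)
    piece = _resize_rgba(fruit.raster, w, h)
    out = n_crop.copy()
    # paste at the corner's position relative to the substrate footprint;
    # cropping the canvas back to the footprint is this clipped composite
    _composite(out, piece, placement.corner[0] - n_x0, placement.corner[1] - n_y0)
    return SyntheticCrop(
        raster=out,
        cls=OcclusionClass.F,
        provenance=Provenance(
            source_image_id=source_image_id,
            element_source_ids=[fruit.source_id],
            element_kinds=[fruit.kind.value],
        ),
    )


# ---------------------------------------------------------------------------
# Fused classes (BL / BF / LF / BLF)

_FUSED_STEPS: dict[OcclusionClass, tuple[ElementKind, ...]] = {
    OcclusionClass.BL: (ElementKind.BRANCH, ElementKind.LEAF),
    OcclusionClass.BF: (ElementKind.FRUIT, ElementKind.BRANCH),
    OcclusionClass.LF: (ElementKind.FRUIT, ElementKind.LEAF),
    OcclusionClass.BLF: (ElementKind.FRUIT, ElementKind.BRANCH, ElementKind.LEAF),
}


def synthesize_fused(
    n_crop: np.ndarray,
    target_cls: OcclusionClass,
    pool: ComponentPool,
    illumination: IlluminationLabel,
    rng: np.random.Generator,
    route: str = "sequential",
    max_overlap: float = DEFAULT_MAX_OVERLAP,
    max_retries: int = DEFAULT_MAX_RETRIES,
    source_image_id: str | None = None,
) -> SyntheticCrop:
    """Synthesize a fused occlusion class.

    ``sequential`` applies the single-element steps in order (fruit
    first where present, so branch/leaf land on top of the occluding
    fruit); ``composite_element`` pastes one pre-segmented composite
    element by the edge-entry rule.
    """
    if target_cls not in _FUSED_STEPS:
        raise SynthesisError(f"{target_cls.code} is not a fused occlusion class")
    if route not in ("sequential", "composite_element"):
        raise ValueError("route must be 'sequential' or 'composite_element'")
    provenance = Provenance(source_image_id=source_image_id)
    raster = n_crop
    if route == "composite_element":
        element = sample_element(pool, ElementKind.COMPOSITE, illumination, rng)
        raster, _ = _paste_edge_entry(
            raster, element, rng, None, DEFAULT_SCALE_RANGE,
            DEFAULT_MIN_SEPARATION, "chebyshev", max_retries,
        )
        provenance.element_source_ids.append(element.source_id)
        provenance.element_kinds.append(element.kind.value)
    else:
        for kind in _FUSED_STEPS[target_cls]:
            element = sample_element(pool, kind, illumination, rng)
            if kind is ElementKind.FRUIT:
                step = synthesize_fruit_occlusion(
                    raster, element, rng, max_overlap, max_retries
                )
            else:
                step = synthesize_single_occluder(
                    raster, element, rng, max_retries=max_retries
                )
            raster = step.raster
            provenance.element_source_ids.extend(step.provenance.element_source_ids)
            provenance.element_kinds.extend(step.provenance.element_kinds)
    return SyntheticCrop(raster=raster, cls=target_cls, provenance=provenance)


# ---------------------------------------------------------------------------
# Substrate extraction


def extract_n_crops(
    dataset: Dataset,
    key: SubDatasetKey,
    count: int,
    rng: np.random.Generator,
    with_source_ids: bool = False,
) -> list:
    """Cut ``count`` unoccluded (class-N) crops from a sub-dataset's images.

    Available N boxes are shuffled once (seeded) and then cycled
    round-robin, so requesting more crops than exist reuses substrates
    as evenly as possible.  With ``with_source_ids`` each entry is a
    ``(raster, image_id)`` pair instead of a bare raster.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    sources: list[tuple] = []
    for record in dataset:
        if record.region != key.region:
            continue
        if record.illumination is not None and record.illumination != key.illumination:
            continue
        for ann in record.annotations:
            if ann.cls is OcclusionClass.N:
                sources.append((record, ann.box))
    if not sources:
        raise SynthesisError(f"no N annotations available for {key.name}")
    order = rng.permutation(len(sources))
    raster_cache: dict[str, np.ndarray] = {}
    out = []
    for i in range(count):
        record, box = sources[int(order[i % len(sources)])]
        if record.image_id not in raster_cache:
            raster_cache[record.image_id] = record.load_raster()
        img = raster_cache[record.image_id]
        crop = img[box.y_min : box.y_max, box.x_min : box.x_max].copy()
        out.append((crop, record.image_id) if with_source_ids else crop)
    return out
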