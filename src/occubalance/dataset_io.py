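"""Detection-dataset I/O: domain types, Pascal VOC XML, YOLO txt, splitting.

Boxes are kept internally in a 0-based, half-open pixel convention
([x_min, x_max) x [y_min, y_max)) so that widths, areas and rectangle
intersections are plain differences.  Pascal VOC's 1-based inclusive
coordinates are converted on read and write; YOLO's normalized
center/size lines are converted exactly on write and to within half a
pixel on read (the format itself quantizes).
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from lxml import etree

from occubalance._seeding import derive_rng
from occubalance.errors import FormatError, ValidationError


class OcclusionClass(enum.Enum):
    """The eight occlusion classes of a fruit annotation.

    N = no occlusion, L = leaf, F = fruit, B = branch, and the four
    fused classes LF, BL, BF, BLF.  The integer value is the fixed
    1-based class index used by the 8-class mAP average; the zero-based
    YOLO index is ``value - 1``.
    """

    N = 1
    L = 2
    F = 3
    B = 4
    LF = 5
    BL = 6
    BF = 7
    BLF = 8

    @property
    def code(self) -> str:
        return self.name

    @property
    def index(self) -> int:
        return self.value

    @classmethod
    def from_code(cls, code: str) -> "OcclusionClass":
        try:
            return cls[code]
        except KeyError:
            raise FormatError(f"unknown occlusion class name: {code!r}") from None

    @property
    def components(self) -> frozenset[str]:
        """The occluder kinds present: subset of {branch, leaf, fruit}."""
        mapping = {"B": "branch", "L": "leaf", "F": "fruit"}
        if self is OcclusionClass.N:
            return frozenset()
        return frozenset(mapping[ch] for ch in self.name)


CLASS_ORDER: tuple[OcclusionClass, ...] = tuple(OcclusionClass)


@dataclass(frozen=True, order=True)
class BBox:
    """Axis-aligned box, 0-based half-open pixel coordinates."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValidationError(f"degenerate box: {self}")
        if self.x_min < 0 or self.y_min < 0:
            raise ValidationError(f"negative coordinate: {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def intersection_area(self, other: "BBox") -> int:
        iw = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        ih = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        return max(iw, 0) * max(ih, 0)

    def iou(self, other: "BBox") -> float:
        inter = self.intersection_area(other)
        union = self.area + other.area - inter
        return inter / union if union else 0.0

    def clipped(self, width: int, height: int) -> "BBox":
        return BBox(
            max(self.x_min, 0),
            max(self.y_min, 0),
            min(self.x_max, width),
            min(self.y_max, height),
        )


@dataclass(frozen=True)
class Annotation:
    """One labeled box on an image."""

    box: BBox
    cls: OcclusionClass


class IlluminationLabel(enum.Enum):
    """Binary illumination condition of an image or element."""

    HIGH = "high"
    LOW = "low"

    @classmethod
    def from_string(cls, s: str) -> "IlluminationLabel":
        try:
            return cls(s.lower())
        except ValueError:
            raise FormatError(f"unknown illumination label: {s!r}") from None


@dataclass(frozen=True)
class SubDatasetKey:
    """One (region, illumination) slice, e.g. ('ZY', high)."""

    region: str
    illumination: IlluminationLabel

    @property
    def name(self) -> str:
        return f"{self.region}_{'H' if self.illumination is IlluminationLabel.HIGH else 'L'}"

    def __lt__(self, other: "SubDatasetKey") -> bool:  # stable iteration order
        return (self.region, self.illumination.value) < (other.region, other.illumination.value)

    def __le__(self, other: "SubDatasetKey") -> bool:
        return self == other or self < other


@dataclass
class ImageRecord:
    """One image with its annotations and provenance tags.

    ``raster`` optionally carries the pixel data for in-memory pipelines
    (fixtures, freshly packed images); otherwise pixels are loaded from
    ``path`` on demand.
    """

    image_id: str
    path: Path | None
    width: int
    height: int
    region: str
    annotations: list[Annotation] = field(default_factory=list)
    illumination: IlluminationLabel | None = None
    raster: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(f"{self.image_id}: non-positive image size")
        for ann in self.annotations:
            b = ann.box
            if b.x_max > self.width or b.y_max > self.height:
                raise ValidationError(
                    f"{self.image_id}: box {b} outside image ({self.width}x{self.height})"
                )

    def load_raster(self) -> np.ndarray:
        """HxWx3 uint8 pixel array, from memory or from ``path``."""
        if self.raster is not None:
            return self.raster
        if self.path is None:
            raise ValidationError(f"{self.image_id}: no raster and no path")
        from PIL import Image

        with Image.open(self.path) as im:
            return np.asarray(im.convert("RGB"))


@dataclass
class Dataset:
    """An ordered collection of image records with unique ids."""

    records: list[ImageRecord] = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self) -> None:
        ids = [r.image_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"{self.name}: duplicate image_ids")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def annotations(self) -> list[Annotation]:
        return [a for r in self.records for a in r.annotations]


# ---------------------------------------------------------------------------
# Pascal VOC XML


def _voc_record_to_xml(record: ImageRecord) -> etree._Element:
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = record.region
    etree.SubElement(root, "filename").text = (
        record.path.name if record.path is not None else f"{record.image_id}.png"
    )
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(record.width)
    etree.SubElement(size, "height").text = str(record.height)
    etree.SubElement(size, "depth").text = "3"
    if record.illumination is not None:
        etree.SubElement(root, "illumination").text = record.illumination.value
    for ann in record.annotations:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = ann.cls.code
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        # internal half-open 0-based -> VOC 1-based inclusive
        etree.SubElement(bnd, "xmin").text = str(ann.box.x_min + 1)
        etree.SubElement(bnd, "ymin").text = str(ann.box.y_min + 1)
        etree.SubElement(bnd, "xmax").text = str(ann.box.x_max)
        etree.SubElement(bnd, "ymax").text = str(ann.box.y_max)
    return root


def write_voc(dataset: Dataset, out_dir: Path | str) -> int:
    """Write one VOC XML per record; returns the number of files written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = 0
    for record in dataset:
        tree = etree.ElementTree(_voc_record_to_xml(record))
        tree.write(
            str(out_dir / f"{record.image_id}.xml"),
            pretty_print=True,
            xml_declaration=False,
            encoding="utf-8",
        )
        n += 1
    return n


def _parse_int(el: etree._Element, tag: str, path: Path) -> int:
    child = el.find(tag)
    if child is None or child.text is None:
        raise FormatError(f"{path}: missing <{tag}>")
    return int(round(float(child.text)))


def read_voc(
    annotation_dir: Path | str,
    image_dir: Path | str | None = None,
    region_map: Mapping[str, str] | None = None,
    default_region: str = "unknown",
    on_invalid_box: str = "reject",
) -> Dataset:
    """Read a directory of Pascal VOC XML files into a :class:`Dataset`.

    The region identifier is taken from the XML ``<folder>`` element,
    overridable per image via ``region_map`` (image_id -> region).
    ``on_invalid_box`` is ``"reject"`` (raise) or ``"clip"`` (clip the box
    to the image bounds).
    """
    annotation_dir = Path(annotation_dir)
    image_dir = Path(image_dir) if image_dir is not None else annotation_dir
    if on_invalid_box not in ("reject", "clip"):
        raise ValueError("on_invalid_box must be 'reject' or 'clip'")
    records: list[ImageRecord] = []
    for xml_path in sorted(annotation_dir.glob("*.xml")):
        root = etree.parse(str(xml_path)).getroot()
        image_id = xml_path.stem
        size_el = root.find("size")
        if size_el is None:
            raise FormatError(f"{xml_path}: missing <size>")
        width = _parse_int(size_el, "width", xml_path)
        height = _parse_int(size_el, "height", xml_path)
        folder_el = root.find("folder")
        region = (
            region_map.get(image_id)
            if region_map and image_id in region_map
            else (folder_el.text if folder_el is not None and folder_el.text else default_region)
        )
        illum_el = root.find("illumination")
        illumination = (
            IlluminationLabel.from_string(illum_el.text)
            if illum_el is not None and illum_el.text
            else None
        )
        annotations: list[Annotation] = []
        for obj in root.findall("object"):
            name_el = obj.find("name")
            if name_el is None or not name_el.text:
                raise FormatError(f"{xml_path}: object without <name>")
            try:
                cls = OcclusionClass.from_code(name_el.text.strip())
            except FormatError:
                raise FormatError(
                    f"{xml_path}: unknown class name {name_el.text.strip()!r}"
                ) from None
            bnd = obj.find("bndbox")
            if bnd is None:
                raise FormatError(f"{xml_path}: object without <bndbox>")
            # VOC 1-based inclusive -> internal half-open 0-based
            box = BBox(
                _parse_int(bnd, "xmin", xml_path) - 1,
                _parse_int(bnd, "ymin", xml_path) - 1,
                _parse_int(bnd, "xmax", xml_path),
                _parse_int(bnd, "ymax", xml_path),
            )
            if box.x_max > width or box.y_max > height:
                if on_invalid_box == "reject":
                    raise ValidationError(
                        f"{xml_path}: box {box} outside image ({width}x{height})"
                    )
                box = box.clipped(width, height)
            annotations.append(Annotation(box, cls))
        filename_el = root.find("filename")
        img_path = (
            image_dir / filename_el.text
            if filename_el is not None and filename_el.text
            else None
        )
        records.append(
            ImageRecord(
                image_id=image_id,
                path=img_path,
                width=width,
                height=height,
                region=region,
                annotations=annotations,
                illumination=illumination,
            )
        )
    return Dataset(records=records, name=annotation_dir.name)


# ---------------------------------------------------------------------------
# YOLO txt


def write_yolo(dataset: Dataset, out_dir: Path | str, precision: int = 6) -> int:
    """Write one YOLO label txt per image (zero-based class, normalized
    cx cy w h); returns the number of files written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = 0
    for record in dataset:
        if record.width <= 0 or record.height <= 0:
            raise ValidationError(f"{record.image_id}: zero-size image")
        lines = []
        for ann in record.annotations:
            b = ann.box
            cx = (b.x_min + b.x_max) / 2 / record.width
            cy = (b.y_min + b.y_max) / 2 / record.height
            w = b.width / record.width
            h = b.height / record.height
            lines.append(
                f"{ann.cls.index - 1} {cx:.{precision}f} {cy:.{precision}f} "
                f"{w:.{precision}f} {h:.{precision}f}"
            )
        (out_dir / f"{record.image_id}.txt").write_text("\n".join(lines) + ("\n" if lines else ""))
        n += 1
    return n


def read_yolo(
    label_dir: Path | str,
    image_sizes: Mapping[str, tuple[int, int]],
    regions: Mapping[str, str] | None = None,
) -> Dataset:
    """Read YOLO label txts back into pixel boxes.

    ``image_sizes`` maps image_id -> (width, height); YOLO files do not
    carry the image size.  Recovered boxes are exact to within half a
    pixel of the originals (format quantization).
    """
    label_dir = Path(label_dir)
    records = []
    for txt_path in sorted(label_dir.glob("*.txt")):
        image_id = txt_path.stem
        if image_id not in image_sizes:
            raise FormatError(f"{txt_path}: no image size known for {image_id!r}")
        width, height = image_sizes[image_id]
        annotations = []
        for lineno, line in enumerate(txt_path.read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 5:
                raise FormatError(f"{txt_path}:{lineno}: expected 5 fields")
            idx = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:])
            cls = CLASS_ORDER[idx]
            x_min = int(round((cx - w / 2) * width))
            y_min = int(round((cy - h / 2) * height))
            x_max = int(round((cx + w / 2) * width))
            y_max = int(round((cy + h / 2) * height))
            annotations.append(Annotation(BBox(x_min, y_min, x_max, y_max), cls))
        records.append(
            ImageRecord(
                image_id=image_id,
                path=None,
                width=width,
                height=height,
                region=(regions or {}).get(image_id, "unknown"),
                annotations=annotations,
            )
        )
    return Dataset(records=records, name=label_dir.name)


# ---------------------------------------------------------------------------
# Manifest and splitting


def write_manifest(dataset: Dataset, path: Path | str) -> None:
    """CSV of (image_id, path, region, illumination) for a dataset."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "path", "region", "illumination"])
        for r in dataset:
            writer.writerow(
                [
                    r.image_id,
                    r.path.name if r.path else "",
                    r.region,
                    r.illumination.value if r.illumination else "",
                ]
            )


def apply_manifest(dataset: Dataset, path: Path | str) -> Dataset:
    """Overlay region / illumination columns of a manifest onto a dataset."""
    rows: dict[str, dict[str, str]] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            rows[row["image_id"]] = row
    records = []
    for r in dataset:
        row = rows.get(r.image_id)
        if row is None:
            records.append(r)
            continue
        records.append(
            replace(
                r,
                region=row.get("region") or r.region,
                illumination=(
                    IlluminationLabel.from_string(row["illumination"])
                    if row.get("illumination")
                    else r.illumination
                ),
            )
        )
    return Dataset(records=records, name=dataset.name)


def read_dataset_dir(path: Path | str) -> Dataset:
    """Read the standard dataset directory layout: images at the top
    level, VOC XML under ``voc/``, optional ``manifest.csv`` overlay."""
    path = Path(path)
    dataset = read_voc(path / "voc", image_dir=path)
    manifest = path / "manifest.csv"
    if manifest.is_file():
        dataset = apply_manifest(dataset, manifest)
    return dataset


def split_train_test(
    dataset: Dataset, test_fraction: float, seed: int
) -> tuple[Dataset, Dataset]:
    """Deterministic by-image split; e.g. ``test_fraction=0.3`` gives the
    conventional 3:7 test:train partition.

    The test size is round-half-up(test_fraction * n); the two outputs are
    disjoint and their union is the input.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(dataset)
    rng = derive_rng(seed, "split_train_test")
    order = rng.permutation(n)
    n_test = int(math.floor(test_fraction * n + 0.5))
    test_idx = set(order[:n_test].tolist())
    train = [r for i, r in enumerate(dataset.records) if i not in test_idx]
    test = [r for i, r in enumerate(dataset.records) if i in test_idx]
    return (
        Dataset(records=train, name=f"{dataset.name}_train"),
        Dataset(records=test, name=f"{dataset.name}_test"),
    )
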