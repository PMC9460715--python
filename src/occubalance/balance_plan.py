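"""Per-cell annotation counts, imbalance statistics and synthesis deficits.

A "cell" is one (sub-dataset, occlusion class) pair, where a sub-dataset
is a (region, illumination) slice.  The plan raises every cell of every
retained sub-dataset to a common target count — by default the largest
cell observed among retained sub-datasets — so each class in each
retained slice contributes equally to training.  Sub-datasets whose
total annotation count falls below a floor are skipped: oversampling a
near-empty slice would clone a handful of source fruits hundreds of
times over.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Mapping

import pandas as pd

from occubalance.dataset_io import (
    CLASS_ORDER,
    Dataset,
    IlluminationLabel,
    OcclusionClass,
    SubDatasetKey,
)
from occubalance.errors import PlanningError

#: Default sub-dataset size floor below which balancing is skipped.
DEFAULT_MIN_BOXES_TO_RETAIN = 1000


@dataclass
class ClassCountTable:
    """Annotation-box counts per (sub-dataset, class), plus image counts."""

    counts: dict[tuple[SubDatasetKey, OcclusionClass], int] = field(default_factory=dict)
    image_counts: dict[SubDatasetKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cell, v in self.counts.items():
            if v < 0:
                raise ValueError(f"negative count at {cell}")

    @property
    def keys(self) -> list[SubDatasetKey]:
        seen = set(self.image_counts) | {k for k, _ in self.counts}
        return sorted(seen)

    def count(self, key: SubDatasetKey, cls: OcclusionClass) -> int:
        return self.counts.get((key, cls), 0)

    def key_total(self, key: SubDatasetKey) -> int:
        return sum(self.count(key, c) for c in CLASS_ORDER)

    def class_total(self, cls: OcclusionClass) -> int:
        return sum(self.count(k, cls) for k in self.keys)

    @property
    def grand_total(self) -> int:
        return sum(self.counts.values())

    # -- CSV round trip (rows = sub-datasets, columns = images, total, classes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in self.keys:
            row = {
                "subdataset": key.name,
                "images": self.image_counts.get(key, 0),
                "total": self.key_total(key),
            }
            row.update({c.code: self.count(key, c) for c in CLASS_ORDER})
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path: Path | str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: Path | str) -> "ClassCountTable":
        df = pd.read_csv(path)
        counts: dict[tuple[SubDatasetKey, OcclusionClass], int] = {}
        image_counts: dict[SubDatasetKey, int] = {}
        for _, row in df.iterrows():
            region, _, illum = str(row["subdataset"]).rpartition("_")
            key = SubDatasetKey(
                region=region,
                illumination=IlluminationLabel.HIGH if illum.upper() == "H" else IlluminationLabel.LOW,
            )
            image_counts[key] = int(row.get("images", 0))
            for c in CLASS_ORDER:
                counts[(key, c)] = int(row[c.code])
        return cls(counts=counts, image_counts=image_counts)


def count_boxes(partition: Mapping[SubDatasetKey, Dataset]) -> ClassCountTable:
    """Tally annotation boxes per (sub-dataset, class) over a partition."""
    counts: dict[tuple[SubDatasetKey, OcclusionClass], int] = {}
    image_counts: dict[SubDatasetKey, int] = {}
    for key, dataset in partition.items():
        image_counts[key] = len(dataset)
        for c in CLASS_ORDER:
            counts[(key, c)] = 0
        for record in dataset:
            for ann in record.annotations:
                counts[(key, ann.cls)] += 1
    return ClassCountTable(counts=counts, image_counts=image_counts)


def _share_1dp(part: int, whole: int) -> float:
    """Percentage share rounded half-up to one decimal place."""
    return float(
        (Decimal(100 * part) / Decimal(whole)).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )


@dataclass
class ImbalanceReport:
    """Class-imbalance summary of a count table.

    Ratios are carried both as exact rationals and as their integer
    floors (the field convention of quoting "~16 times" differences).
    """

    per_class_totals: dict[OcclusionClass, int]
    grand_total: int
    per_class_share: dict[OcclusionClass, float]
    class_ratio: Fraction | None
    class_ratio_floor: int | None
    retained_cell_ratio: Fraction | None
    retained_cell_ratio_floor: int | None
    shares_defined: bool


def imbalance_report(
    table: ClassCountTable,
    min_boxes_to_retain: int = DEFAULT_MIN_BOXES_TO_RETAIN,
) -> ImbalanceReport:
    """Per-class totals, percentage shares, and max/min imbalance ratios.

    ``class_ratio`` is largest-class total over smallest nonzero class
    total across the whole table; ``retained_cell_ratio`` is the largest
    cell over the smallest nonzero cell restricted to sub-datasets whose
    totals reach ``min_boxes_to_retain``.
    """
    totals = {c: table.class_total(c) for c in CLASS_ORDER}
    grand = table.grand_total
    shares_defined = grand > 0
    shares = {
        c: (_share_1dp(t, grand) if shares_defined else float("nan"))
        for c, t in totals.items()
    }
    nonzero = [t for t in totals.values() if t > 0]
    class_ratio = Fraction(max(nonzero), min(nonzero)) if nonzero else None
    retained = [k for k in table.keys if table.key_total(k) >= min_boxes_to_retain]
    cells = [table.count(k, c) for k in retained for c in CLASS_ORDER]
    nz_cells = [v for v in cells if v > 0]
    cell_ratio = Fraction(max(nz_cells), min(nz_cells)) if nz_cells else None
    return ImbalanceReport(
        per_class_totals=totals,
        grand_total=grand,
        per_class_share=shares,
        class_ratio=class_ratio,
        class_ratio_floor=int(class_ratio) if class_ratio else None,
        retained_cell_ratio=cell_ratio,
        retained_cell_ratio_floor=int(cell_ratio) if cell_ratio else None,
        shares_defined=shares_defined,
    )


@dataclass
class BalancePlan:
    """Synthesis deficits raising every retained cell to ``target``."""

    target: int
    retained_keys: set[SubDatasetKey]
    skipped_keys: set[SubDatasetKey]
    deficits: dict[tuple[SubDatasetKey, OcclusionClass], int]

    def __post_init__(self) -> None:
        if self.target <= 0:
            raise PlanningError("balance target must be positive")
        if self.retained_keys & self.skipped_keys:
            raise PlanningError("a key cannot be both retained and skipped")
        for cell, d in self.deficits.items():
            if d < 0:
                raise PlanningError(f"negative deficit at {cell}")

    def deficit(self, key: SubDatasetKey, cls: OcclusionClass) -> int:
        return self.deficits.get((key, cls), 0)

    def key_deficit_total(self, key: SubDatasetKey) -> int:
        return sum(self.deficit(key, c) for c in CLASS_ORDER)

    @property
    def total_to_synthesize(self) -> int:
        return sum(self.deficits.values())

    def to_json(self, path: Path | str | None = None) -> str:
        obj = {
            "target": self.target,
            "retained_keys": sorted(k.name for k in self.retained_keys),
            "skipped_keys": sorted(k.name for k in self.skipped_keys),
            "deficits": {
                k.name: {c.code: self.deficit(k, c) for c in CLASS_ORDER}
                for k in sorted(self.retained_keys)
            },
        }
        text = json.dumps(obj, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "BalancePlan":
        obj = json.loads(text)

        def parse_key(name: str) -> SubDatasetKey:
            region, _, illum = name.rpartition("_")
            return SubDatasetKey(
                region=region,
                illumination=IlluminationLabel.HIGH if illum == "H" else IlluminationLabel.LOW,
            )

        deficits = {
            (parse_key(kname), OcclusionClass.from_code(code)): int(v)
            for kname, per_cls in obj["deficits"].items()
            for code, v in per_cls.items()
        }
        return cls(
            target=int(obj["target"]),
            retained_keys={parse_key(n) for n in obj["retained_keys"]},
            skipped_keys={parse_key(n) for n in obj["skipped_keys"]},
            deficits=deficits,
        )


def make_balance_plan(
    table: ClassCountTable,
    min_boxes_to_retain: int = DEFAULT_MIN_BOXES_TO_RETAIN,
    target: int | None = None,
) -> BalancePlan:
    """Plan per-cell synthesis deficits toward a common target.

    Sub-datasets with fewer than ``min_boxes_to_retain`` total boxes are
    skipped.  The target defaults to the maximum cell count among
    retained sub-datasets; every retained cell's deficit is
    ``target - count`` so that count + deficit == target exactly.
    """
    retained = {k for k in table.keys if table.key_total(k) >= min_boxes_to_retain}
    skipped = {k for k in table.keys if k not in retained}
    if not retained:
        raise PlanningError(
            f"no sub-dataset reaches {min_boxes_to_retain} boxes; nothing to balance"
        )
    if target is None:
        target = max(table.count(k, c) for k in retained for c in CLASS_ORDER)
    if target <= 0:
        raise PlanningError("balance target must be positive")
    deficits: dict[tuple[SubDatasetKey, OcclusionClass], int] = {}
    for key in sorted(retained):
        for c in CLASS_ORDER:
            current = table.count(key, c)
            if current > target:
                raise PlanningError(
                    f"cell {key.name}/{c.code} count {current} exceeds target {target}"
                )
            deficits[(key, c)] = target - current
    return BalancePlan(
        target=target, retained_keys=retained, skipped_keys=skipped, deficits=deficits
    )
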