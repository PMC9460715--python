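"""Detection evaluation: precision, recall, per-class AP and 8-class mAP.

The conventions are PASCAL-VOC style: a prediction matches an unmatched
ground-truth box of the same class when their IoU reaches the threshold
(default 0.5); predictions are consumed in descending confidence order;
each ground-truth box can be matched at most once.  Then

    P = TP / (TP + FP),      R = TP / (TP + FN),
    AP = area under the interpolated precision-recall curve,
    mAP = (1/8) * sum of the eight per-class APs,

with AP computed by all-point interpolation of the precision envelope
(the 11-point variant is available behind a flag).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from occubalance.dataset_io import (
    CLASS_ORDER,
    Annotation,
    BBox,
    Dataset,
    OcclusionClass,
)
from occubalance.errors import ValidationError

DEFAULT_IOU_THRESHOLD = 0.5
DEFAULT_CONFIDENCE_THRESHOLD = 0.5
N_CLASSES = len(CLASS_ORDER)


@dataclass(frozen=True)
class Detection:
    """One predicted box with class and confidence."""

    image_id: str
    box: BBox
    cls: OcclusionClass
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class MatchCounts:
    """True/false positives and false negatives for one class."""

    TP: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValidationError("negative match count")


@dataclass
class PRCurve:
    """Precision-recall points swept over the confidence ranking."""

    points: list[tuple[float, float]]  # (recall, precision), recall non-decreasing
    n_gt: int


@dataclass
class APResult:
    """Per-class AP and their 8-class mean."""

    per_class_ap: dict[OcclusionClass, float]
    map: float


def gt_by_image(dataset: Dataset) -> dict[str, list[Annotation]]:
    """Ground-truth annotations keyed by image id."""
    return {r.image_id: list(r.annotations) for r in dataset}


def _greedy_tp_flags(
    gt: Mapping[str, Sequence[Annotation]],
    preds: Sequence[Detection],
    cls: OcclusionClass,
    iou_threshold: float,
) -> tuple[np.ndarray, int]:
    """TP flag per class prediction (confidence-ordered) and the GT count."""
    gt_boxes: dict[str, list[BBox]] = {
        img: [a.box for a in anns if a.cls is cls] for img, anns in gt.items()
    }
    n_gt = sum(len(v) for v in gt_boxes.values())
    matched: dict[str, list[bool]] = {img: [False] * len(v) for img, v in gt_boxes.items()}
    cls_preds = sorted(
        (p for p in preds if p.cls is cls), key=lambda p: -p.confidence
    )
    flags = np.zeros(len(cls_preds), dtype=bool)
    for i, pred in enumerate(cls_preds):
        candidates = gt_boxes.get(pred.image_id, [])
        best_iou, best_j = 0.0, -1
        for j, box in enumerate(candidates):
            if matched[pred.image_id][j]:
                continue
            iou = pred.box.iou(box)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[pred.image_id][best_j] = True
            flags[i] = True
    return flags, n_gt


def match_detections(
    gt: Mapping[str, Sequence[Annotation]],
    preds: Sequence[Detection],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> dict[OcclusionClass, MatchCounts]:
    """Greedy confidence-ordered matching, per class.

    Unmatched predictions are FP; unmatched ground truth are FN; the
    counts conserve boxes: TP+FN = #gt of the class, TP+FP = #preds.
    """
    out: dict[OcclusionClass, MatchCounts] = {}
    for cls in CLASS_ORDER:
        flags, n_gt = _greedy_tp_flags(gt, preds, cls, iou_threshold)
        tp = int(flags.sum())
        out[cls] = MatchCounts(TP=tp, FP=len(flags) - tp, FN=n_gt - tp)
    return out


def precision_recall(counts: MatchCounts) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); zero denominators yield 0."""
    p = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else 0.0
    r = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else 0.0
    return p, r


def pr_curve(
    gt: Mapping[str, Sequence[Annotation]],
    preds: Sequence[Detection],
    cls: OcclusionClass,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> PRCurve:
    """Cumulative precision/recall along the confidence ranking."""
    flags, n_gt = _greedy_tp_flags(gt, preds, cls, iou_threshold)
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    points = []
    for i in range(len(flags)):
        precision = tp_cum[i] / (tp_cum[i] + fp_cum[i])
        recall = tp_cum[i] / n_gt if n_gt else 0.0
        points.append((float(recall), float(precision)))
    return PRCurve(points=points, n_gt=n_gt)


def average_precision(curve: PRCurve, method: str = "all_point") -> float:
    """Area under the interpolated precision envelope vs recall.

    ``all_point``: sum over recall increments of the maximum precision at
    that recall or beyond.  ``11point``: mean of the envelope sampled at
    recalls 0, 0.1, ..., 1.0.
    """
    if method not in ("all_point", "11point"):
        raise ValueError("method must be 'all_point' or '11point'")
    if not curve.points:
        return 0.0
    recalls = np.array([r for r, _ in curve.points])
    precisions = np.array([p for _, p in curve.points])
    # monotone non-increasing precision envelope, right to left
    envelope = np.maximum.accumulate(precisions[::-1])[::-1]
    if method == "11point":
        return float(
            np.mean(
                [
                    envelope[recalls >= t].max(initial=0.0) if (recalls >= t).any() else 0.0
                    for t in np.linspace(0, 1, 11)
                ]
            )
        )
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recalls, envelope):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def mean_average_precision(per_class_ap: Mapping[OcclusionClass, float]) -> float:
    """1/8 of the sum of the eight per-class APs."""
    if set(per_class_ap) != set(CLASS_ORDER):
        raise ValidationError("mAP needs exactly the 8 occlusion-class APs")
    return (1 / N_CLASSES) * sum(per_class_ap.values())


@dataclass
class EvaluationReport:
    """Aggregate P/R at a confidence cutoff plus AP per class and mAP."""

    precision: float
    recall: float
    per_class_ap: dict[OcclusionClass, float]
    map: float
    iou_threshold: float
    confidence_threshold: float

    def to_frame(self) -> pd.DataFrame:
        row = {"P": self.precision, "R": self.recall, "mAP_0.5": self.map}
        row.update({f"AP_{c.code}": self.per_class_ap[c] for c in CLASS_ORDER})
        return pd.DataFrame([row])


def evaluate(
    gt: Mapping[str, Sequence[Annotation]] | Dataset,
    preds: Sequence[Detection],
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    ap_method: str = "all_point",
) -> EvaluationReport:
    """Full evaluation: AP/mAP from the confidence sweep; the aggregate P
    and R are computed over all classes at ``confidence_threshold``."""
    if isinstance(gt, Dataset):
        gt = gt_by_image(gt)
    per_class_ap = {
        cls: average_precision(pr_curve(gt, preds, cls, iou_threshold), ap_method)
        for cls in CLASS_ORDER
    }
    cut = [p for p in preds if p.confidence >= confidence_threshold]
    counts = match_detections(gt, cut, iou_threshold)
    tp = sum(c.TP for c in counts.values())
    fp = sum(c.FP for c in counts.values())
    fn = sum(c.FN for c in counts.values())
    agg = MatchCounts(TP=tp, FP=fp, FN=fn)
    precision, recall = precision_recall(agg)
    return EvaluationReport(
        precision=precision,
        recall=recall,
        per_class_ap=per_class_ap,
        map=mean_average_precision(per_class_ap),
        iou_threshold=iou_threshold,
        confidence_threshold=confidence_threshold,
    )


# ---------------------------------------------------------------------------
# Prediction file I/O (JSON lines: image_id, cls, confidence, box)


def write_predictions(preds: Sequence[Detection], path: Path | str) -> None:
    with Path(path).open("w") as fh:
        for p in preds:
            fh.write(
                json.dumps(
                    {
                        "image_id": p.image_id,
                        "cls": p.cls.code,
                        "confidence": p.confidence,
                        "box": [p.box.x_min, p.box.y_min, p.box.x_max, p.box.y_max],
                    }
                )
                + "\n"
            )


def read_predictions(path: Path | str) -> list[Detection]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        out.append(
            Detection(
                image_id=obj["image_id"],
                box=BBox(*obj["box"]),
                cls=OcclusionClass.from_code(obj["cls"]),
                confidence=float(obj["confidence"]),
            )
        )
    return out
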