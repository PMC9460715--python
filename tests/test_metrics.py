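"""Precision/recall arithmetic, AP integration and the 8-class mAP."""

import itertools

import numpy as np
import pytest

from occubalance.dataset_io import (
    CLASS_ORDER,
    Annotation,
    BBox,
    OcclusionClass,
)
from occubalance.errors import ValidationError
from occubalance.metrics import (
    Detection,
    MatchCounts,
    PRCurve,
    average_precision,
    evaluate,
    match_detections,
    mean_average_precision,
    pr_curve,
    precision_recall,
    read_predictions,
    write_predictions,
)


def _det(image_id, box, cls, conf):
    return Detection(image_id, BBox(*box), cls, conf)


def _gt(image_id, boxes, cls=OcclusionClass.N):
    return {image_id: [Annotation(BBox(*b), cls) for b in boxes]}


class TestMatching:
    def test_perfect_predictions(self):
        gt = _gt("i", [(0, 0, 10, 10), (20, 20, 40, 40)])
        preds = [
            _det("i", (0, 0, 10, 10), OcclusionClass.N, 0.9),
            _det("i", (20, 20, 40, 40), OcclusionClass.N, 0.8),
        ]
        counts = match_detections(gt, preds)[OcclusionClass.N]
        assert (counts.TP, counts.FP, counts.FN) == (2, 0, 0)

    def test_no_predictions(self):
        gt = _gt("i", [(0, 0, 10, 10)] * 1)
        counts = match_detections(gt, [])[OcclusionClass.N]
        assert (counts.TP, counts.FP, counts.FN) == (0, 0, 1)

    def test_class_mismatch_is_fp_and_fn(self):
        gt = _gt("i", [(0, 0, 10, 10)], OcclusionClass.B)
        preds = [_det("i", (0, 0, 10, 10), OcclusionClass.L, 0.9)]
        counts = match_detections(gt, preds)
        assert counts[OcclusionClass.B].FN == 1
        assert counts[OcclusionClass.L].FP == 1

    def test_conservation_identity(self, rng):
        gt = {}
        preds = []
        for img in ("a", "b", "c"):
            boxes = []
            for _ in range(int(rng.integers(0, 5))):
                x0, y0 = int(rng.integers(0, 80)), int(rng.integers(0, 80))
                boxes.append((x0, y0, x0 + int(rng.integers(5, 20)), y0 + int(rng.integers(5, 20))))
            gt.update(_gt(img, boxes, OcclusionClass.F))
            for _ in range(int(rng.integers(0, 6))):
                x0, y0 = int(rng.integers(0, 80)), int(rng.integers(0, 80))
                preds.append(
                    _det(img, (x0, y0, x0 + 10, y0 + 10), OcclusionClass.F, float(rng.random()))
                )
        counts = match_detections(gt, preds)[OcclusionClass.F]
        n_gt = sum(len(v) for v in gt.values())
        assert counts.TP + counts.FN == n_gt
        assert counts.TP + counts.FP == len(preds)

    def test_greedy_matches_exhaustive_oracle_on_small_case(self):
        """3 GT / 4 preds: greedy confidence-ordered TP count equals the
        best achievable over all per-prediction match orders."""
        gt_boxes = [(0, 0, 10, 10), (12, 0, 22, 10), (0, 12, 10, 22)]
        pred_boxes = [
            ((0, 0, 10, 10), 0.95),
            ((1, 0, 11, 10), 0.90),   # overlaps gt0 heavily too
            ((12, 1, 22, 11), 0.85),
            ((50, 50, 60, 60), 0.80),  # matches nothing
        ]
        gt = _gt("i", gt_boxes)
        preds = [_det("i", b, OcclusionClass.N, c) for b, c in pred_boxes]
        counts = match_detections(gt, preds, iou_threshold=0.5)[OcclusionClass.N]

        best_tp = 0
        for order in itertools.permutations(range(len(pred_boxes))):
            used = set()
            tp = 0
            for i in order:
                pb = BBox(*pred_boxes[i][0])
                for j, g in enumerate(gt_boxes):
                    if j not in used and pb.iou(BBox(*g)) >= 0.5:
                        used.add(j)
                        tp += 1
                        break
            best_tp = max(best_tp, tp)
        assert counts.TP == best_tp == 2
        assert counts.FP == 2 and counts.FN == 1


class TestPrecisionRecall:
    def test_direct_formula(self):
        assert precision_recall(MatchCounts(8, 2, 2)) == (0.8, 0.8)

    def test_zero_tp(self):
        assert precision_recall(MatchCounts(0, 5, 0)) == (0.0, 0.0)

    @pytest.mark.parametrize("tp,fp,fn", [(3, 1, 2), (0, 0, 4), (10, 0, 0), (1, 9, 9)])
    def test_matches_independent_recomputation(self, tp, fp, fn):
        p, r = precision_recall(MatchCounts(tp, fp, fn))
        assert p == (tp / (tp + fp) if tp + fp else 0.0)
        assert r == (tp / (tp + fn) if tp + fn else 0.0)


class TestAveragePrecision:
    def test_perfect_detector(self):
        curve = PRCurve(points=[(0.5, 1.0), (1.0, 1.0)], n_gt=2)
        assert average_precision(curve) == pytest.approx(1.0)

    def test_single_point_half_recall(self):
        curve = PRCurve(points=[(0.5, 1.0)], n_gt=2)
        assert average_precision(curve) == pytest.approx(0.5)

    def test_empty_curve(self):
        assert average_precision(PRCurve(points=[], n_gt=3)) == 0.0

    def test_matches_step_sum_oracle_on_random_curves(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 20))
            flags = rng.random(n) < 0.5
            n_gt = max(1, int(flags.sum()) + int(rng.integers(0, 4)))
            tp = np.cumsum(flags)
            fp = np.cumsum(~flags)
            points = [(tp[i] / n_gt, tp[i] / (tp[i] + fp[i])) for i in range(n)]
            curve = PRCurve(points=points, n_gt=n_gt)
            # independent envelope oracle: max precision at recall >= r over
            # every distinct recall break
            recalls = sorted({r for r, _ in points})
            ap_oracle, prev = 0.0, 0.0
            for r in recalls:
                env = max(p for rr, p in points if rr >= r)
                ap_oracle += (r - prev) * env
                prev = r
            assert average_precision(curve) == pytest.approx(ap_oracle)

    def test_duplicate_lower_confidence_tp_never_decreases_ap(self):
        gt = _gt("i", [(0, 0, 10, 10), (20, 20, 30, 30)])
        preds = [_det("i", (0, 0, 10, 10), OcclusionClass.N, 0.9)]
        base = average_precision(pr_curve(gt, preds, OcclusionClass.N))
        more = preds + [_det("i", (20, 20, 30, 30), OcclusionClass.N, 0.3)]
        extended = average_precision(pr_curve(gt, more, OcclusionClass.N))
        assert extended >= base


class TestMeanAveragePrecision:
    def test_all_ones(self):
        assert mean_average_precision({c: 1.0 for c in CLASS_ORDER}) == 1.0

    def test_all_halves(self):
        assert mean_average_precision({c: 0.5 for c in CLASS_ORDER}) == 0.5

    def test_eighth_factor_is_mean(self, rng):
        aps = {c: float(rng.random()) for c in CLASS_ORDER}
        assert mean_average_precision(aps) == pytest.approx(0.125 * sum(aps.values()))

    def test_requires_exactly_eight(self):
        with pytest.raises(ValidationError):
            mean_average_precision({OcclusionClass.N: 1.0})


class TestEvaluate:
    def test_perfect_fixture_detector(self, toy_dataset, rng):
        from occubalance.fixtures import generate_fixture_predictions

        preds = generate_fixture_predictions(toy_dataset, quality=1.0, rng=rng)
        report = evaluate(toy_dataset, preds)
        assert report.precision == 1.0
        assert report.recall == 1.0
        assert report.map == pytest.approx(1.0)

    def test_prediction_file_round_trip(self, tmp_path):
        preds = [
            _det("a", (0, 0, 10, 10), OcclusionClass.BF, 0.25),
            _det("b", (5, 5, 9, 9), OcclusionClass.N, 1.0),
        ]
        write_predictions(preds, tmp_path / "p.jsonl")
        assert read_predictions(tmp_path / "p.jsonl") == preds
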