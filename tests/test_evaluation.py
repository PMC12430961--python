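"""Average precision vs. a brute-force enumeration oracle, regression and
threshold diagnostics arithmetic, confusion-matrix accounting."""

import numpy as np
import pytest

from stripnet.head_loss import iou_xyxy
from stripnet.evaluation import (
    average_precision, evaluate_detections, regression_metrics,
    threshold_diagnostics, strip_confusion, run_ablation, ABLATION_ORDER,
)


def brute_force_ap(dets, gts, iou_thr=0.5):
    """Independent oracle: for every top-k prefix recompute greedy matching
    from scratch, collect (recall, precision) points, integrate the
    precision envelope over recall."""
    dets = sorted(dets, key=lambda d: -d["conf"])
    n_gt = len(gts)
    if n_gt == 0 or not dets:
        return 0.0
    points = []
    for k in range(1, len(dets) + 1):
        used = set()
        tp = 0
        for d in dets[:k]:
            best, best_iou = None, iou_thr
            for gi, g in enumerate(gts):
                if gi in used or g["image_id"] != d["image_id"]:
                    continue
                iou = float(iou_xyxy(np.asarray(d["box"], float),
                                     np.asarray(g["box"], float)))
                if iou >= best_iou:
                    best, best_iou = gi, iou + 1e-12
            if best is not None:
                used.add(best)
                tp += 1
        points.append((tp / n_gt, tp / k))
    recalls = np.array([p[0] for p in points])
    precisions = np.array([p[1] for p in points])
    r = np.concatenate([[0.0], recalls])
    p = np.concatenate([[1.0], precisions])
    for i in range(p.size - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.nonzero(np.diff(r) > 0)[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def _box(x, y, s=10):
    return (x, y, x + s, y + s)


class TestAveragePrecision:
    def test_single_true_positive_is_perfect(self):
        gts = [dict(image_id=0, class_id=0, box=_box(0, 0))]
        dets = [dict(image_id=0, class_id=0, conf=0.9, box=_box(0, 0))]
        assert average_precision(dets, gts)["map"] == pytest.approx(1.0)

    def test_high_confidence_fp_halves_ap(self):
        """FP at conf 0.9 then TP at 0.8 on one GT: PR points (0,0), (1,0.5)
        integrate to AP 0.5."""
        gts = [dict(image_id=0, class_id=0, box=_box(0, 0))]
        dets = [dict(image_id=0, class_id=0, conf=0.9, box=_box(50, 50)),
                dict(image_id=0, class_id=0, conf=0.8, box=_box(0, 0))]
        assert average_precision(dets, gts)["map"] == pytest.approx(0.5)

    def test_duplicate_detection_counts_as_fp(self):
        gts = [dict(image_id=0, class_id=0, box=_box(0, 0))]
        dets = [dict(image_id=0, class_id=0, conf=0.9, box=_box(0, 0)),
                dict(image_id=0, class_id=0, conf=0.8, box=_box(0, 0))]
        res = average_precision(dets, gts)
        assert res["map"] == pytest.approx(1.0)  # TP first, FP after full recall
        _, flags = None, None
        # explicit: two detections, only one can match
        recalls, precisions = res["pr_curves"][0]
        assert recalls[-1] == pytest.approx(1.0)
        assert precisions[-1] == pytest.approx(0.5)

    def test_matches_brute_force_oracle_on_random_instances(self):
        """100 random instances with <= 20 detections: exact agreement with
        the exhaustive prefix-enumeration oracle."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_gt = int(rng.integers(1, 6))
            n_det = int(rng.integers(0, 21))
            gts = [dict(image_id=int(rng.integers(3)), class_id=0,
                        box=_box(*rng.uniform(0, 80, 2)))
                   for _ in range(n_gt)]
            dets = [dict(image_id=int(rng.integers(3)), class_id=0,
                         conf=float(rng.random()),
                         box=_box(*rng.uniform(0, 80, 2)))
                    for _ in range(n_det)]
            got = average_precision(dets, gts)["map"]
            want = brute_force_ap(dets, gts)
            assert got == pytest.approx(want, abs=1e-9)

    def test_appending_weakest_fp_never_increases_ap(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            gts = [dict(image_id=0, class_id=0, box=_box(*rng.uniform(0, 60, 2)))
                   for _ in range(3)]
            dets = [dict(image_id=0, class_id=0, conf=float(rng.uniform(0.3, 1)),
                         box=_box(*rng.uniform(0, 60, 2))) for _ in range(6)]
            base = average_precision(dets, gts)["map"]
            worse = dets + [dict(image_id=0, class_id=0, conf=0.01,
                                 box=_box(200, 200))]
            assert average_precision(worse, gts)["map"] <= base + 1e-12
            assert 0.0 <= base <= 1.0

    def test_detections_without_gt_class_score_zero(self):
        gts = [dict(image_id=0, class_id=0, box=_box(0, 0))]
        dets = [dict(image_id=0, class_id=0, conf=0.9, box=_box(0, 0)),
                dict(image_id=0, class_id=1, conf=0.9, box=_box(0, 0))]
        res = average_precision(dets, gts)
        assert res["per_class"][1] == 0.0


class TestRegressionMetrics:
    def test_perfect_predictions(self):
        m = regression_metrics([1, 2, 3], [1, 2, 3])
        assert m["mae"] == 0.0 and m["r2"] == pytest.approx(1.0)

    def test_hand_computed_toy_vectors(self):
        """true (0,50,100), pred (10,50,90): MAE 20/3, R^2 = 1 - 200/5000."""
        m = regression_metrics([10, 50, 90], [0, 50, 100])
        assert m["mae"] == pytest.approx(20 / 3, rel=1e-9)
        assert m["mae"] == pytest.approx(6.667, abs=1e-3)
        assert m["r2"] == pytest.approx(0.96, rel=1e-9)

    def test_constant_truth_flags_undefined_r2(self):
        m = regression_metrics([1, 2, 3], [5, 5, 5])
        assert m["r2"] is None and m["pearson_r"] is None

    def test_r2_equals_pearson_squared_for_affine_predictions(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(0, 100, 30)
        p = 0.9 * t + 4.0
        m = regression_metrics(p, t)
        # affine predictions: Pearson r is exactly 1, R^2 <= 1
        assert m["pearson_r"] == pytest.approx(1.0, abs=1e-12)
        # classical identity: predictions that are the least-squares affine
        # fit of truth on a feature satisfy R^2 = r^2
        x = t + rng.normal(0, 5, 30)
        b, a = np.polyfit(x, t, 1)
        fit = a + b * x
        m3 = regression_metrics(fit, t)
        assert m3["r2"] == pytest.approx(m3["pearson_r"] ** 2, abs=1e-9)

    def test_empty_or_mismatched_rejected(self):
        with pytest.raises(ValueError):
            regression_metrics([], [])
        with pytest.raises(ValueError):
            regression_metrics([1], [1, 2])


class TestThresholdDiagnostics:
    def test_perfect_predictions_all_rates_one(self):
        d = threshold_diagnostics([10, 60, 120], [12, 55, 130])
        for thr, row in d.items():
            if row["tp"] + row["fn"]:
                assert row["sensitivity"] == 1.0
            if row["tn"] + row["fp"]:
                assert row["specificity"] == 1.0

    def test_hand_enumerated_two_by_two(self):
        """true (10,30,60,20), pred (12,28,55,30) at t=25:
        TP 2, FN 0, TN 1, FP 1."""
        d = threshold_diagnostics([12, 28, 55, 30], [10, 30, 60, 20],
                                  thresholds=(25.0,))[25.0]
        assert (d["tp"], d["fn"], d["tn"], d["fp"]) == (2, 0, 1, 1)
        assert d["sensitivity"] == pytest.approx(1.0)
        assert d["specificity"] == pytest.approx(0.5)
        assert d["ppv"] == pytest.approx(2 / 3)
        assert d["npv"] == pytest.approx(1.0)

    def test_all_negative_truth_flags_sensitivity_undefined(self):
        d = threshold_diagnostics([1, 2], [1, 2], thresholds=(25.0,))[25.0]
        assert d["sensitivity"] is None
        assert d["tp"] + d["fn"] == 0

    def test_empty_vectors_rejected(self):
        with pytest.raises(ValueError):
            threshold_diagnostics([], [])


class TestConfusion:
    def test_row_sums_equal_truth_counts(self):
        true = [-1, -1, 0, 1, 2, 2]
        pred = [-1, 0, 0, None, 2, 1]
        cm = strip_confusion(pred, true, n_bins=3)
        assert cm.sum() == len(true)
        assert cm[0].sum() == 2      # negatives
        assert cm[3].sum() == 2      # bin 2
        assert cm[2, 4] == 1         # bin-1 truth judged invalid

    def test_diagonal_counts_correct_predictions(self):
        cm = strip_confusion([-1, 0, 1], [-1, 0, 1], n_bins=2)
        assert cm[0, 0] == 1 and cm[1, 1] == 1 and cm[2, 2] == 1


class TestAblationValidation:
    def test_unknown_toggle_rejected(self):
        with pytest.raises(ValueError):
            run_ablation(None, None, None, toggles=("warp-drive",))

    def test_livt_requires_cfpn(self):
        with pytest.raises(ValueError):
            run_ablation(None, None, None, toggles=("LIVT",))

    def test_order_is_canonical(self):
        assert ABLATION_ORDER == ("C-FPN", "LIVT", "S-5", "SimAM")
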