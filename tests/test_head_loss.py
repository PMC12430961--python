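"""Composite-loss oracles: DFL scalar cases and simplex minimum, BCE
arithmetic, CIoU against analytic and Monte-Carlo IoU, task-aligned
assignment behaviour, and head output contracts."""

import numpy as np
import pytest

from stripnet.nn import Tensor
from stripnet.backbone import FeatureMap
from stripnet.head_loss import (
    REG_MAX, LAMBDAS, BoxDistribution, LossBreakdown, Head,
    dfl_loss, cls_loss, ciou_loss, iou_xyxy, assign_targets, total_loss,
    DetectionLoss, decode_boxes, make_anchors,
)


def onehot_probs(idx, reg_max=REG_MAX):
    p = np.zeros(reg_max)
    p[idx] = 1.0
    return p


class TestDFL:
    def test_point_mass_at_integral_target_is_zero(self):
        assert dfl_loss(onehot_probs(3), 3.0) == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_fractional_case(self):
        """p=3.4 with (S3, S4) = (0.6, 0.4):
        -(0.6 ln 0.6 + 0.4 ln 0.4) = 0.67301..."""
        probs = np.zeros(REG_MAX)
        probs[3], probs[4] = 0.6, 0.4
        want = -(0.6 * np.log(0.6) + 0.4 * np.log(0.4))
        assert dfl_loss(probs, 3.4) == pytest.approx(want, abs=1e-6)
        assert dfl_loss(probs, 3.4) == pytest.approx(0.6730, abs=1e-4)

    def test_minimized_at_linear_interpolation_distribution(self):
        """Grid search over the (S3, S4) simplex at step 1e-3: the loss is
        minimal where S3 = p_hi - p = 0.6."""
        p = 3.4
        grid = np.arange(1e-3, 1.0, 1e-3)
        losses = []
        for s3 in grid:
            probs = np.zeros(REG_MAX)
            probs[3], probs[4] = s3, 1.0 - s3
            losses.append(dfl_loss(probs, p))
        best = grid[int(np.argmin(losses))]
        assert best == pytest.approx(0.6, abs=1e-3)

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError):
            dfl_loss(onehot_probs(0), -0.5)
        with pytest.raises(ValueError):
            dfl_loss(onehot_probs(0), REG_MAX - 0.5)

    def test_top_edge_target_supported(self):
        assert dfl_loss(onehot_probs(REG_MAX - 1), float(REG_MAX - 1)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_box_distribution_expectation_decoding(self):
        """A symmetric distribution around bin m decodes to expectation m."""
        logits = np.full((4, REG_MAX), -40.0)
        logits[:, 4] = 2.0
        logits[:, 6] = 2.0   # symmetric around 5
        dist = BoxDistribution(logits)
        assert np.allclose(dist.expectation(), 5.0, atol=1e-6)
        assert np.allclose(dist.probs().sum(axis=-1), 1.0)


class TestClsLoss:
    def test_exact_prediction_is_zero_after_clamp(self):
        y = np.array([1.0, 0.0, 0.0])
        assert cls_loss(y, y) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_half_gives_three_ln_two(self):
        y_hat = np.full(3, 0.5)
        y = np.array([0.0, 1.0, 0.0])
        assert cls_loss(y_hat, y) == pytest.approx(3 * np.log(2), rel=1e-9)

    def test_hand_computed_two_class_case(self):
        got = cls_loss(np.array([0.9, 0.1]), np.array([1.0, 0.0]))
        assert got == pytest.approx(-2 * np.log(0.9), rel=1e-9)
        assert got == pytest.approx(0.2107, abs=1e-4)


class TestCIoU:
    def test_identical_boxes_zero_loss(self):
        assert ciou_loss((0, 0, 2, 2), (0, 0, 2, 2)) == pytest.approx(0.0)

    def test_hand_computed_overlap_case(self):
        """pred (0,0,2,2) vs gt (1,1,3,3): IoU 1/7, rho^2 2, c^2 18,
        square aspect ratios so v=0; loss = 6/7 + 1/9."""
        got = ciou_loss((0, 0, 2, 2), (1, 1, 3, 3))
        assert got == pytest.approx(6 / 7 + 1 / 9, rel=1e-9)
        assert got == pytest.approx(0.9683, abs=1e-4)

    def test_disjoint_boxes_exceed_one(self):
        assert ciou_loss((0, 0, 1, 1), (5, 5, 6, 6)) > 1.0

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            ciou_loss((0, 0, 0, 1), (0, 0, 1, 1))

    def test_iou_term_matches_monte_carlo_rasterization(self):
        """On 200 random box pairs, the analytic IoU inside ciou_loss agrees
        with a 10^6-point Monte-Carlo rasterization within 2e-3."""
        rng = np.random.default_rng(123)
        n_pts = 1_000_000
        for _ in range(200):
            a = np.sort(rng.uniform(0, 10, 4).reshape(2, 2), axis=0)
            b = np.sort(rng.uniform(0, 10, 4).reshape(2, 2), axis=0)
            boxa = (a[0, 0], a[0, 1], a[1, 0] + 0.2, a[1, 1] + 0.2)
            boxb = (b[0, 0], b[0, 1], b[1, 0] + 0.2, b[1, 1] + 0.2)
            lo = np.minimum(boxa[:2], boxb[:2])
            hi = np.maximum(boxa[2:], boxb[2:])
            pts = rng.uniform(lo, hi, size=(n_pts, 2))
            in_a = np.all((pts >= boxa[:2]) & (pts <= boxa[2:]), axis=1)
            in_b = np.all((pts >= boxb[:2]) & (pts <= boxb[2:]), axis=1)
            union = np.count_nonzero(in_a | in_b)
            mc_iou = np.count_nonzero(in_a & in_b) / union if union else 0.0
            assert float(iou_xyxy(np.array(boxa), np.array(boxb))) == \
                pytest.approx(mc_iou, abs=2e-3)


class TestTotalLoss:
    def test_unit_components_give_weighted_sum(self):
        assert total_loss(1.0, 1.0, 1.0).total == pytest.approx(2.5)

    def test_perfect_predictions_give_zero(self):
        assert total_loss(0.0, 0.0, 0.0).total == 0.0

    def test_hand_computed_composite(self):
        bd = total_loss(0.6730, 2.0794, 0.9683)
        want = 1.5 * 0.6730 + 0.5 * 2.0794 + 0.5 * 0.9683
        assert bd.total == pytest.approx(want, rel=1e-9)
        assert bd.total == pytest.approx(2.5334, abs=1e-3)

    def test_exact_lambda_linearity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c = rng.uniform(0, 5, 3)
            bd = total_loss(a, b, c)
            assert bd.total == LAMBDAS[0] * a + LAMBDAS[1] * b + LAMBDAS[2] * c

    def test_components_nonnegative_enforced_by_construction(self):
        bd = LossBreakdown(0.1, 0.2, 0.3)
        assert bd.total == pytest.approx(1.5 * 0.1 + 0.5 * 0.2 + 0.5 * 0.3)


class TestAssignment:
    def _setup(self, n=8):
        anchors = np.stack([np.linspace(5, 75, n), np.full(n, 40.0)], axis=1)
        return anchors

    def test_no_ground_truth_all_background(self):
        anchors = self._setup()
        asg = assign_targets(np.zeros((8, 2)), np.zeros((8, 4)), anchors,
                             np.zeros((0, 4)), np.zeros(0))
        assert np.all(asg.gt_index == -1)

    def test_dominant_iou_anchor_wins_topk1(self):
        anchors = self._setup()
        gt = np.array([[0.0, 30.0, 80.0, 50.0]])
        pred = np.tile([2.0, 32.0, 20.0, 48.0], (8, 1))
        pred[3] = [1.0, 31.0, 79.0, 49.0]        # near-perfect box
        scores = np.full((8, 1), 0.5)
        asg = assign_targets(scores, pred, anchors, gt, np.array([0]), topk=1)
        assert asg.matched.tolist() == [3]

    def test_tied_alignment_prefers_lower_anchor_index(self):
        anchors = self._setup(4)
        gt = np.array([[0.0, 30.0, 80.0, 50.0]])
        pred = np.tile([10.0, 30.0, 70.0, 50.0], (4, 1))   # identical boxes
        scores = np.full((4, 1), 0.5)
        asg = assign_targets(scores, pred, anchors, gt, np.array([0]), topk=1)
        assert asg.matched.tolist() == [0]

    def test_anchor_outside_all_boxes_is_background(self):
        anchors = np.array([[100.0, 100.0]])
        gt = np.array([[0.0, 0.0, 10.0, 10.0]])
        asg = assign_targets(np.full((1, 1), 0.9), np.array([[0, 0, 10, 10.0]]),
                             anchors, gt, np.array([0]))
        assert np.all(asg.gt_index == -1)


class TestHeadForward:
    def _head_out(self, zero=False):
        rng = np.random.default_rng(0)
        head = Head(8, n_classes=5, rng=rng)
        if zero:
            head.cls_out.weight.data[...] = 0
            head.cls_out.bias.data[...] = 0
            head.reg_out.weight.data[...] = 0
            head.reg_out.bias.data[...] = 0
        feats = {s: FeatureMap(Tensor(rng.normal(
            size=(1, 8, 40 // (s // 8), 40 // (s // 8))).astype(np.float32)), s)
            for s in (8, 16, 32)}
        return head, head(feats)

    def test_output_shapes_per_level(self):
        _, out = self._head_out()
        cls40, reg40 = out[8]
        assert cls40.shape == (1, 5, 40, 40)
        assert reg40.shape == (1, 4 * REG_MAX, 40, 40)
        # 1600 locations x (5 cls + 64 reg) logits at the stride-8 level
        assert cls40.data.reshape(5, -1).shape[1] == 1600

    def test_wrong_level_count_rejected(self):
        head = Head(8, n_classes=5, rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            head({8: FeatureMap(Tensor(np.zeros((1, 8, 4, 4),
                                                dtype=np.float32)), 8)})

    def test_zeroed_head_gives_uniform_side_distributions(self):
        _, out = self._head_out(zero=True)
        _, reg = out[32]
        probs = np.exp(reg.data.reshape(4, REG_MAX, -1))
        probs /= probs.sum(axis=1, keepdims=True)
        assert np.allclose(probs, 1.0 / REG_MAX)

    def test_point_mass_decodes_to_bin_times_stride(self):
        probs = np.zeros((1, 4, REG_MAX))
        probs[0, :, 3] = 1.0
        anchors = np.array([[100.0, 100.0]])
        strides = np.array([8.0])
        box = decode_boxes(probs, anchors, strides)[0]
        assert np.allclose(box, [100 - 24, 100 - 24, 100 + 24, 100 + 24])


class TestDetectionLossBatch:
    def test_matches_scalar_definitions_on_crafted_case(self):
        """The batched training loss reproduces the scalar BCE on an
        unmatched (all-background) case exactly."""
        rng = np.random.default_rng(0)
        cls_logits = Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32))
        reg_logits = Tensor(rng.normal(size=(1, 4 * REG_MAX, 4, 4))
                            .astype(np.float32))
        crit = DetectionLoss(n_classes=2)
        head_out = {8: (cls_logits, reg_logits),
                    16: (Tensor(np.zeros((1, 2, 2, 2), dtype=np.float32)),
                         Tensor(np.zeros((1, 4 * REG_MAX, 2, 2),
                                         dtype=np.float32))),
                    32: (Tensor(np.zeros((1, 2, 1, 1), dtype=np.float32)),
                         Tensor(np.zeros((1, 4 * REG_MAX, 1, 1),
                                         dtype=np.float32)))}
        total, bd = crit(head_out, [dict(boxes=np.zeros((0, 4)),
                                         classes=np.zeros(0))])
        # no matches: the BCE sum over all anchors is normalized by 1
        want = 0.0
        for cl, _ in head_out.values():
            conf = 1 / (1 + np.exp(-cl.data.reshape(2, -1).T))
            want += cls_loss(conf, np.zeros_like(conf))
        assert bd.l_cls == pytest.approx(want, rel=1e-4)
        assert bd.l_dfl == 0.0 and bd.l_box == 0.0
        assert float(total.data) == pytest.approx(0.5 * bd.l_cls, rel=1e-6)

    def test_breakdown_total_is_lambda_linear(self):
        bd = LossBreakdown(0.3, 0.7, 1.1)
        assert bd.total == pytest.approx(1.5 * 0.3 + 0.5 * 0.7 + 0.5 * 1.1)

    def test_gradients_flow_to_matched_case(self):
        rng = np.random.default_rng(1)
        cls_logits = Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32),
                            requires_grad=True)
        reg_logits = Tensor(rng.normal(size=(1, 4 * REG_MAX, 4, 4))
                            .astype(np.float32), requires_grad=True)
        zeros8 = lambda c: Tensor(np.zeros((1, c, 2, 2), dtype=np.float32))
        zeros32 = lambda c: Tensor(np.zeros((1, c, 1, 1), dtype=np.float32))
        head_out = {8: (cls_logits, reg_logits),
                    16: (zeros8(2), zeros8(4 * REG_MAX)),
                    32: (zeros32(2), zeros32(4 * REG_MAX))}
        crit = DetectionLoss(n_classes=2)
        total, bd = crit(head_out, [dict(boxes=np.array([[4.0, 4.0, 28.0, 28.0]]),
                                         classes=np.array([1]))])
        total.backward()
        assert bd.l_box > 0 and bd.l_dfl > 0
        assert np.any(reg_logits.grad != 0)
        assert np.any(cls_logits.grad != 0)
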