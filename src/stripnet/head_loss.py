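"""Anchor-free decoupled detection head, task-aligned assignment, and the
composite training loss

    L = lambda1 * l_dfl + lambda2 * l_cls + lambda3 * l_box,
    (lambda1, lambda2, lambda3) = (1.5, 0.5, 0.5)

with distribution focal loss for box-side regression over Reg_max = 16
discrete bins, binary cross-entropy over one-hot class labels, and
complete-IoU for localization.

Scalar numpy implementations (`dfl_loss`, `cls_loss`, `ciou_loss`,
`total_loss`) define the arithmetic; `DetectionLoss` is the batched
autodiff version used in training and matches them term by term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, Module, Conv2d, ConvBNSiLU

__all__ = [
    "REG_MAX", "LAMBDAS", "BoxDistribution", "LossBreakdown", "Assignment",
    "Head", "dfl_loss", "cls_loss", "ciou_loss", "iou_xyxy", "assign_targets",
    "total_loss", "DetectionLoss", "decode_boxes", "make_anchors",
]

REG_MAX = 16
LAMBDAS = (1.5, 0.5, 0.5)
_EPS_CONF = 1e-7


@dataclass
class BoxDistribution:
    """Discrete distributions over side offsets: logits (4, REG_MAX),
    one row per box side (left, top, right, bottom), bin centers
    p_i = i in stride units."""

    logits: np.ndarray
    reg_max: int = REG_MAX

    def probs(self) -> np.ndarray:
        z = self.logits - self.logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def expectation(self) -> np.ndarray:
        """Expected offset per side, in stride units."""
        return self.probs() @ np.arange(self.reg_max)


@dataclass
class LossBreakdown:
    l_dfl: float
    l_cls: float
    l_box: float
    lambda1: float = LAMBDAS[0]
    lambda2: float = LAMBDAS[1]
    lambda3: float = LAMBDAS[2]
    total: float = field(default=None)

    def __post_init__(self):
        if self.total is None:
            self.total = (self.lambda1 * self.l_dfl + self.lambda2 * self.l_cls
                          + self.lambda3 * self.l_box)


@dataclass
class Assignment:
    """anchor index -> ground-truth index matching; -1 marks background."""

    gt_index: np.ndarray        # (n_anchors,) int
    scores: np.ndarray          # (n_anchors,) alignment score of the match

    @property
    def matched(self) -> np.ndarray:
        return np.nonzero(self.gt_index >= 0)[0]


class Head(Module):
    """Decoupled classification/regression head shared across levels.

    Per level: a 3x3 conv stem per branch, then a 1x1 conv emitting
    `n_classes` logits (classification) or 4*REG_MAX logits (regression).
    """

    def __init__(self, width: int, n_classes: int, reg_max: int = REG_MAX,
                 rng=None):
        self.n_classes = n_classes
        self.reg_max = reg_max
        self.cls_stem = ConvBNSiLU(width, width, 3, rng=rng)
        self.cls_out = Conv2d(width, n_classes, 1, rng=rng)
        self.reg_stem = ConvBNSiLU(width, width, 3, rng=rng)
        self.reg_out = Conv2d(width, 4 * reg_max, 1, rng=rng)
        # bias the side distributions toward small offsets at init: the
        # expected object extent is a few stride units, and starting the
        # softmax expectation near 7.5 bins slows localization badly
        prior = -0.5 * np.arange(reg_max, dtype=np.float32)
        self.reg_out.bias.data[...] = np.tile(prior, 4)

    def forward(self, feats: dict) -> dict:
        if len(feats) != 3:
            raise ValueError("head expects exactly three feature levels")
        out = {}
        for stride, fmap in feats.items():
            x = fmap.values
            out[stride] = (self.cls_out(self.cls_stem(x)),
                           self.reg_out(self.reg_stem(x)))
        return out


# ---------------------------------------------------------------------------
# scalar loss definitions
# ---------------------------------------------------------------------------

def dfl_loss(side_probs: np.ndarray, p: float, reg_max: int = REG_MAX) -> float:
    """Distribution focal loss for one box side.

    `side_probs` is the predicted probability vector over the `reg_max`
    bins, `p` the continuous target offset in bin (stride) units.  With
    i = floor(p):  l = -[(i+1-p) ln S_i + (p-i) ln S_{i+1}].
    """
    if not 0 <= p <= reg_max - 1:
        raise ValueError(f"target offset {p} outside [0, {reg_max - 1}]")
    s = np.asarray(side_probs, dtype=np.float64)
    i = min(int(np.floor(p)), reg_max - 2)
    wl, wr = (i + 1 - p), (p - i)
    return float(-(wl * np.log(max(s[i], _EPS_CONF))
                   + wr * np.log(max(s[i + 1], _EPS_CONF))))


def cls_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Binary cross-entropy summed over classes (and anchors, if batched).

    `pred` holds per-class confidences in (0,1); values are clamped to
    [1e-7, 1-1e-7] before the logs.
    """
    y_hat = np.clip(np.asarray(pred, dtype=np.float64), _EPS_CONF, 1 - _EPS_CONF)
    y = np.asarray(target, dtype=np.float64)
    return float(-(y * np.log(y_hat) + (1 - y) * np.log(1 - y_hat)).sum())


def iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of corner-format boxes, shapes (..., 4)."""
    a, b = np.asarray(a, np.float64), np.asarray(b, np.float64)
    ix1 = np.maximum(a[..., 0], b[..., 0])
    iy1 = np.maximum(a[..., 1], b[..., 1])
    ix2 = np.minimum(a[..., 2], b[..., 2])
    iy2 = np.minimum(a[..., 3], b[..., 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
    area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
    return inter / (area_a + area_b - inter + 1e-12)


def ciou_loss(box_pred, box_gt) -> float:
    """Complete-IoU loss: 1 - IoU + rho^2/c^2 + alpha*v (corner boxes)."""
    p = np.asarray(box_pred, dtype=np.float64)
    g = np.asarray(box_gt, dtype=np.float64)
    if p[2] <= p[0] or p[3] <= p[1] or g[2] <= g[0] or g[3] <= g[1]:
        raise ValueError("degenerate box")
    iou = float(iou_xyxy(p, g))
    pcx, pcy = (p[0] + p[2]) / 2, (p[1] + p[3]) / 2
    gcx, gcy = (g[0] + g[2]) / 2, (g[1] + g[3]) / 2
    rho2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    ex1, ey1 = min(p[0], g[0]), min(p[1], g[1])
    ex2, ey2 = max(p[2], g[2]), max(p[3], g[3])
    c2 = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2
    wp, hp = p[2] - p[0], p[3] - p[1]
    wg, hg = g[2] - g[0], g[3] - g[1]
    v = (4 / np.pi ** 2) * (np.arctan(wg / hg) - np.arctan(wp / hp)) ** 2
    alpha = 0.0 if v == 0 else v / ((1 - iou) + v)
    return float(1 - iou + rho2 / c2 + alpha * v)


def total_loss(l_dfl: float, l_cls: float, l_box: float) -> LossBreakdown:
    return LossBreakdown(l_dfl=float(l_dfl), l_cls=float(l_cls),
                         l_box=float(l_box))


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def assign_targets(scores: np.ndarray, pred_boxes: np.ndarray,
                   anchor_points: np.ndarray, gt_boxes: np.ndarray,
                   gt_classes: np.ndarray, a: float = 0.5, b: float = 6.0,
                   topk: int = 10, anchor_strides: np.ndarray = None) -> Assignment:
    """Task-aligned assignment.

    Alignment of anchor j with ground truth g is t = score^a * IoU^b using
    the anchor's confidence for the ground-truth class and the IoU of its
    decoded box.  Candidates are anchors whose center lies inside the
    ground-truth box; each ground truth takes its top-k by alignment
    (ties: higher IoU, then lower anchor index); anchors claimed by
    several ground truths keep the highest-alignment claim; everything
    else is background.

    When `anchor_strides` is given, the inside-test expands each box to at
    least one stride per axis around its centre, so objects thinner than
    the anchor grid spacing (the strip bands) still receive candidates,
    and each object is gated to the pyramid levels matching its scale
    (larger side in (s, 8s] per stride s, unbounded at the coarsest), so
    thin bands do not train coarse heads into emitting sloppy duplicates.
    """
    n_anchors = anchor_points.shape[0]
    gt_index = np.full(n_anchors, -1, dtype=np.int64)
    out_scores = np.zeros(n_anchors)
    if len(gt_boxes) == 0:
        return Assignment(gt_index, out_scores)
    max_stride = anchor_strides.max() if anchor_strides is not None else None
    for g, (box, cls) in enumerate(zip(gt_boxes, gt_classes)):
        if anchor_strides is not None:
            cx, cy = (box[0] + box[2]) / 2, (box[1] + box[3]) / 2
            hw = np.maximum((box[2] - box[0]) / 2, anchor_strides / 2)
            hh = np.maximum((box[3] - box[1]) / 2, anchor_strides / 2)
            side = max(box[2] - box[0], box[3] - box[1])
            # scale ranges: stride s owns sides in (4s, 8s]; the finest
            # level has no lower bound, the coarsest no upper bound
            in_range = (((side <= 8 * anchor_strides)
                         | (anchor_strides == max_stride))
                        & ((side > 4 * anchor_strides)
                           | (anchor_strides == anchor_strides.min())))
            inside = (in_range
                      & (anchor_points[:, 0] > cx - hw)
                      & (anchor_points[:, 0] < cx + hw)
                      & (anchor_points[:, 1] > cy - hh)
                      & (anchor_points[:, 1] < cy + hh))
        else:
            inside = ((anchor_points[:, 0] > box[0]) & (anchor_points[:, 0] < box[2])
                      & (anchor_points[:, 1] > box[1]) & (anchor_points[:, 1] < box[3]))
        cand = np.nonzero(inside)[0]
        if cand.size == 0:
            continue
        ious = iou_xyxy(pred_boxes[cand], box[None, :])
        conf = scores[cand, int(cls)]
        align = np.power(np.clip(conf, 0, None), a) * np.power(ious, b)
        # sort by (alignment desc, IoU desc, index asc)
        order = np.lexsort((cand, -ious, -align))
        take = order[:topk]
        for j in take:
            idx = cand[j]
            if gt_index[idx] < 0 or align[j] > out_scores[idx]:
                gt_index[idx] = g
                out_scores[idx] = align[j]
    return Assignment(gt_index, out_scores)


# ---------------------------------------------------------------------------
# batched training loss
# ---------------------------------------------------------------------------

def make_anchors(shapes: dict) -> tuple:
    """Anchor centers in image pixels for {stride: (H, W)} levels.

    Returns (points (n,2), strides (n,)) ordered by ascending stride.
    """
    pts, sts = [], []
    for stride in sorted(shapes):
        h, w = shapes[stride]
        ys, xs = np.mgrid[0:h, 0:w]
        pts.append(np.stack([(xs.ravel() + 0.5) * stride,
                             (ys.ravel() + 0.5) * stride], axis=1))
        sts.append(np.full(h * w, stride, dtype=np.float64))
    return np.concatenate(pts), np.concatenate(sts)


def decode_boxes(reg_probs: np.ndarray, anchor_points: np.ndarray,
                 strides: np.ndarray) -> np.ndarray:
    """Expectation-decode (n, 4, REG_MAX) side distributions to corner boxes."""
    bins = np.arange(reg_probs.shape[-1])
    sides = (reg_probs * bins).sum(axis=-1) * strides[:, None]  # l, t, r, b
    x1 = anchor_points[:, 0] - sides[:, 0]
    y1 = anchor_points[:, 1] - sides[:, 1]
    x2 = anchor_points[:, 0] + sides[:, 2]
    y2 = anchor_points[:, 1] + sides[:, 3]
    return np.stack([x1, y1, x2, y2], axis=1)


class DetectionLoss:
    """Differentiable composite loss over a batch of head outputs."""

    def __init__(self, n_classes: int, reg_max: int = REG_MAX,
                 lambdas=LAMBDAS, assigner_kwargs=None):
        self.n_classes = n_classes
        self.reg_max = reg_max
        self.lambdas = lambdas
        self.assigner_kwargs = assigner_kwargs or {}

    def _flatten(self, head_out: dict):
        """Concatenate per-level maps to (N, n_anchors, ...) tensors."""
        cls_list, reg_list, shapes = [], [], {}
        for stride in sorted(head_out):
            cls_map, reg_map = head_out[stride]
            n, nc, h, w = cls_map.shape
            shapes[stride] = (h, w)
            cls_list.append(cls_map.reshape(n, nc, h * w).transpose(0, 2, 1))
            reg_list.append(reg_map.reshape(n, 4, self.reg_max, h * w)
                            .transpose(0, 3, 1, 2))
        from .nn import concat as cat
        return cat(cls_list, axis=1), cat(reg_list, axis=1), shapes

    def __call__(self, head_out: dict, targets: list):
        """`targets`: per image, dict(boxes=(m,4) pixel corners, classes=(m,))."""
        cls_t, reg_t, shapes = self._flatten(head_out)
        anchor_points, strides = make_anchors(shapes)
        n_img, n_anchor, _ = cls_t.shape
        bins = np.arange(self.reg_max, dtype=np.float32)

        probs_np = _softmax_np(reg_t.data, axis=-1)
        scores_np = 1.0 / (1.0 + np.exp(-np.clip(cls_t.data, -80, 80)))

        cls_targets = np.zeros((n_img, n_anchor, self.n_classes), dtype=np.float32)
        matched_rows = []          # flat (img * n_anchor + anchor)
        matched_gt_boxes = []
        matched_side_targets = []
        for i, tgt in enumerate(targets):
            gt_boxes = np.asarray(tgt["boxes"], dtype=np.float64).reshape(-1, 4)
            gt_cls = np.asarray(tgt["classes"], dtype=np.int64).reshape(-1)
            pred_boxes = decode_boxes(probs_np[i], anchor_points, strides)
            asg = assign_targets(scores_np[i], pred_boxes, anchor_points,
                                 gt_boxes, gt_cls, anchor_strides=strides,
                                 **self.assigner_kwargs)
            for j in asg.matched:
                g = asg.gt_index[j]
                cls_targets[i, j, gt_cls[g]] = 1.0
                box = gt_boxes[g]
                s = strides[j]
                sides = np.array([anchor_points[j, 0] - box[0],
                                  anchor_points[j, 1] - box[1],
                                  box[2] - anchor_points[j, 0],
                                  box[3] - anchor_points[j, 1]]) / s
                sides = np.clip(sides, 0.0, self.reg_max - 1 - 1e-3)
                matched_rows.append(i * n_anchor + j)
                matched_gt_boxes.append(box)
                matched_side_targets.append(sides)

        # classification: BCE over every anchor and class, normalized by
        # the matched-anchor count so positives are not drowned by the
        # background majority
        conf = cls_t.sigmoid().clip(_EPS_CONF, 1 - _EPS_CONF)
        y = cls_targets
        bce = -(Tensor(y) * conf.log() + Tensor(1.0 - y) * (1.0 - conf).log())
        n_matched = max(len(matched_rows), 1)
        l_cls = bce.sum() * (1.0 / n_matched)

        if matched_rows:
            rows = np.asarray(matched_rows)
            side_t = np.asarray(matched_side_targets)           # (m, 4)
            gt_arr = np.asarray(matched_gt_boxes)               # (m, 4)
            m = len(rows)
            reg_flat = reg_t.reshape(n_img * n_anchor, 4, self.reg_max)
            sel = reg_flat.gather_rows(rows)                    # (m, 4, R)
            logp = sel.softmax(axis=-1).clip(_EPS_CONF, 1.0).log()
            i_lo = np.minimum(np.floor(side_t), self.reg_max - 2).astype(np.int64)
            wl = (i_lo + 1 - side_t).astype(np.float32)
            wr = (side_t - i_lo).astype(np.float32)
            onehot_lo = np.zeros((m, 4, self.reg_max), dtype=np.float32)
            onehot_hi = np.zeros((m, 4, self.reg_max), dtype=np.float32)
            mi, si = np.indices((m, 4))
            onehot_lo[mi, si, i_lo] = wl
            onehot_hi[mi, si, i_lo + 1] = wr
            l_dfl = -(logp * Tensor(onehot_lo + onehot_hi)).sum() * (1.0 / (4 * m))

            # CIoU on expectation-decoded boxes
            probs = sel.softmax(axis=-1)
            sides = (probs * Tensor(bins)).sum(axis=-1)          # (m, 4)
            s_m = strides[rows % n_anchor][:, None].astype(np.float32)
            a_m = anchor_points[rows % n_anchor].astype(np.float32)
            sides = sides * Tensor(s_m)
            x1 = Tensor(a_m[:, 0]) - _col(sides, 0)
            y1 = Tensor(a_m[:, 1]) - _col(sides, 1)
            x2 = Tensor(a_m[:, 0]) + _col(sides, 2)
            y2 = Tensor(a_m[:, 1]) + _col(sides, 3)
            l_box = _ciou_tensor(x1, y1, x2, y2, gt_arr).mean()
        else:
            l_dfl = Tensor(np.zeros(()))
            l_box = Tensor(np.zeros(()))

        l1, l2, l3 = self.lambdas
        total = l_dfl * l1 + l_cls * l2 + l_box * l3
        breakdown = LossBreakdown(float(l_dfl.data), float(l_cls.data),
                                  float(l_box.data))
        return total, breakdown


def _col(t: Tensor, i: int) -> Tensor:
    def bw(g):
        full = np.zeros_like(t.data)
        full[:, i] = g
        t._accum(full)

    return Tensor._make(t.data[:, i], (t,), bw)


def _ciou_tensor(x1, y1, x2, y2, gt: np.ndarray) -> Tensor:
    g = gt.astype(np.float32)
    gx1, gy1, gx2, gy2 = (Tensor(g[:, 0]), Tensor(g[:, 1]),
                          Tensor(g[:, 2]), Tensor(g[:, 3]))
    ix1 = x1.maximum(gx1)
    iy1 = y1.maximum(gy1)
    ix2 = x2.minimum(gx2)
    iy2 = y2.minimum(gy2)
    zero = Tensor(np.zeros(1, dtype=np.float32))
    iw = (ix2 - ix1).maximum(zero)
    ih = (iy2 - iy1).maximum(zero)
    inter = iw * ih
    area_p = ((x2 - x1).maximum(zero)) * ((y2 - y1).maximum(zero))
    area_g = (gx2 - gx1) * (gy2 - gy1)
    iou = inter / (area_p + area_g - inter + 1e-9)
    pcx, pcy = (x1 + x2) * 0.5, (y1 + y2) * 0.5
    gcx, gcy = (gx1 + gx2) * 0.5, (gy1 + gy2) * 0.5
    rho2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    ex1, ey1 = x1.minimum(gx1), y1.minimum(gy1)
    ex2, ey2 = x2.maximum(gx2), y2.maximum(gy2)
    c2 = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2 + 1e-9
    wp = (x2 - x1).maximum(Tensor(np.full(1, 1e-6, dtype=np.float32)))
    hp = (y2 - y1).maximum(Tensor(np.full(1, 1e-6, dtype=np.float32)))
    wg, hg = gx2 - gx1, gy2 - gy1
    v = ((wg / hg).arctan() - (wp / hp).arctan()) ** 2 * (4.0 / np.pi ** 2)
    # alpha is treated as a constant w.r.t. gradients
    iou_c = iou.data
    v_c = v.data
    alpha = np.where(v_c > 0, v_c / ((1 - iou_c) + v_c + 1e-9), 0.0)
    return 1.0 - iou + rho2 / c2 + v * Tensor(alpha.astype(np.float32))


def _softmax_np(x: np.ndarray, axis=-1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
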