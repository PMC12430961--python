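"""Training and inference pipeline.

Covers reference-spot exposure normalization, the augmentation policy
(rotation +-10 deg, translation +-10 px, brightness +-20%, mosaic with a
mosaic-free tail of the schedule), SGD training with a 3-epoch linear
warmup and early stopping on validation mAP@0.5, anchor-free decoding with
per-class NMS, and the detection -> concentration readout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from PIL import Image
from scipy import ndimage

from .nn import Tensor, SGD
from .model import Detector, ModelConfig
from .head_loss import (DetectionLoss, decode_boxes, make_anchors,
                        _softmax_np, iou_xyxy)
from .synthetic import (BoxLabel, ConcentrationBinning, ChromogenicLaw,
                        read_labels, NEGATIVE_CLASS, C_LINE_CLASS,
                        _MEMBRANE, _BAND_FULL)

__all__ = [
    "TrainConfig", "ReferenceSpot", "Detection", "normalize_exposure",
    "augment", "mosaic4", "Trainer", "train", "detect", "nms",
    "predict_concentration", "refine_concentration", "StripDataset",
    "save_checkpoint", "load_checkpoint", "lr_at",
]


@dataclass
class TrainConfig:
    lr0: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch: int = 8
    epochs: int = 50
    warmup_epochs: int = 3
    mosaic_off_last: int = 10
    mosaic_prob: float = 0.5
    patience: int = 10
    seed: int = 0
    rotation_deg: float = 10.0
    translation_px: float = 10.0
    brightness: float = 0.2
    grad_clip: float = 10.0
    cos_lr: bool = False        # post-warmup: constant (default) or cosine

    def __post_init__(self):
        if self.warmup_epochs >= self.epochs:
            raise ValueError("warmup_epochs must be < epochs")
        for name in ("lr0", "batch", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ReferenceSpot:
    region: tuple               # (x1, y1, x2, y2) pixel rectangle
    standard_gray: float = 250.0
    tolerance: float = 10.0

    def __post_init__(self):
        if not 0 < self.standard_gray < 255:
            raise ValueError("standard_gray must lie in (0, 255)")


@dataclass
class Detection:
    box: tuple                  # (x1, y1, x2, y2) pixels
    class_id: int
    confidence: float

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if x2 <= x1 or y2 <= y1:
            raise ValueError("detection box must have positive area")
        if not 0 <= self.confidence <= 1:
            raise ValueError("confidence outside [0, 1]")


# ---------------------------------------------------------------------------
# exposure normalization
# ---------------------------------------------------------------------------

def normalize_exposure(image: np.ndarray, spots) -> tuple:
    """Reference-spot grayscale normalization.

    Computes the mean gray level over the spot regions; within tolerance of
    the standard the image passes through ('normal'), otherwise a single
    multiplicative gain standard/measured is applied ('overexposed' /
    'underexposed' verdicts), clipped to [0, 255].
    """
    img = np.asarray(image)
    h, w = img.shape[:2]
    grays = []
    for spot in spots:
        x1, y1, x2, y2 = spot.region
        if not (0 <= x1 < x2 <= w and 0 <= y1 < y2 <= h):
            raise ValueError(f"reference spot {spot.region} outside image")
        grays.append(img[y1:y2, x1:x2].astype(np.float64).mean())
    g = float(np.mean(grays))
    std = spots[0].standard_gray
    tol = spots[0].tolerance
    if abs(g - std) <= tol:
        return img.copy(), "normal"
    gain = std / g
    verdict = "overexposed" if g > std else "underexposed"
    out = np.clip(img.astype(np.float64) * gain, 0, 255).astype(img.dtype)
    return out, verdict


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _affine_image_and_boxes(img, labels, angle_deg, tx, ty, bright):
    h, w = img.shape[:2]
    out = img.astype(np.float64)
    if abs(angle_deg) > 1e-9:
        out = ndimage.rotate(out, -angle_deg, axes=(0, 1), reshape=False,
                             order=1, mode="nearest")
    if abs(tx) > 1e-9 or abs(ty) > 1e-9:
        out = ndimage.shift(out, (ty, tx, 0), order=1, mode="nearest")
    out = np.clip(out * bright, 0, 255)

    th = np.deg2rad(angle_deg)
    rotm = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    c0 = np.array([(w - 1) / 2, (h - 1) / 2])
    new_labels = []
    for b in labels:
        x1, y1, x2, y2 = b.to_xyxy(w, h)
        corners = np.array([[x1, y1], [x2, y1], [x1, y2], [x2, y2]]) - c0
        rc = corners @ rotm.T + c0 + (tx, ty)
        nx1, ny1 = rc[:, 0].min(), rc[:, 1].min()
        nx2, ny2 = rc[:, 0].max(), rc[:, 1].max()
        nx1, nx2 = np.clip([nx1, nx2], 0, w)
        ny1, ny2 = np.clip([ny1, ny2], 0, h)
        if nx2 - nx1 >= 2 and ny2 - ny1 >= 2:
            new_labels.append(BoxLabel.from_xyxy(b.class_id, nx1, ny1,
                                                 nx2, ny2, w, h))
    return out.astype(np.uint8), new_labels


def augment(image: np.ndarray, labels, cfg: TrainConfig, rng) -> tuple:
    """Seeded rotation/translation/brightness augmentation.

    Boxes are transformed consistently (rotated corners -> enclosing box)
    and reclipped; a draw that pushes every box out of frame is rejected
    and redrawn (at most 10 tries, then identity).
    """
    for _ in range(10):
        ang = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
        tx = rng.uniform(-cfg.translation_px, cfg.translation_px)
        ty = rng.uniform(-cfg.translation_px, cfg.translation_px)
        br = rng.uniform(1 - cfg.brightness, 1 + cfg.brightness)
        img, lbl = _affine_image_and_boxes(image, labels, ang, tx, ty, br)
        if lbl or not labels:
            return img, lbl
    return image.copy(), list(labels)


def mosaic4(samples) -> tuple:
    """2x2 mosaic of four (image, labels) samples at the common size."""
    assert len(samples) == 4
    h, w = samples[0][0].shape[:2]
    canvas = np.zeros((h, w, 3), dtype=np.uint8)
    out_labels = []
    hh, hw = h // 2, w // 2
    offsets = [(0, 0), (0, hw), (hh, 0), (hh, hw)]
    for (img, labels), (oy, ox) in zip(samples, offsets):
        small = np.asarray(Image.fromarray(img).resize((hw, hh), Image.BILINEAR))
        canvas[oy:oy + hh, ox:ox + hw] = small
        for b in labels:
            x1, y1, x2, y2 = b.to_xyxy(w, h)
            out_labels.append(BoxLabel.from_xyxy(
                b.class_id, x1 / 2 + ox, y1 / 2 + oy,
                x2 / 2 + ox, y2 / 2 + oy, w, h))
    return canvas, out_labels


# ---------------------------------------------------------------------------
# dataset access
# ---------------------------------------------------------------------------

class StripDataset:
    """In-memory view over a generated dataset directory + manifest.

    By default images pass through reference-spot exposure normalization
    at load time — the photometric preprocessing the detector is meant to
    see, making band darkness comparable across illumination conditions.
    """

    def __init__(self, root, split: str | None = None,
                 normalize: bool = True):
        self.root = root
        self.normalize = normalize
        with open(os.path.join(root, "manifest.yaml")) as fh:
            self.manifest = yaml.safe_load(fh)
        entries = self.manifest["entries"]
        if split:
            keep = set(self.manifest["splits"][split])
            entries = [e for e in entries if e["image"] in keep]
        self.entries = entries
        self.class_names = self.manifest["class_names"]
        self.binning = ConcentrationBinning(
            tuple(self.manifest["binning"]["edges"]),
            tuple(self.manifest["binning"]["representative"]))
        self._cache = {}

    def __len__(self):
        return len(self.entries)

    def load(self, i: int) -> tuple:
        e = self.entries[i]
        if i not in self._cache:
            img = np.asarray(Image.open(os.path.join(self.root, e["image"])))
            if self.normalize and e.get("reference_spots"):
                spots = [ReferenceSpot(tuple(r))
                         for r in e["reference_spots"]]
                img, _ = normalize_exposure(img, spots)
            labels = read_labels(os.path.join(self.root, e["label"]))
            self._cache[i] = (img, labels)
        img, labels = self._cache[i]
        return img.copy(), list(labels), e


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def lr_at(step: int, steps_per_epoch: int, cfg: TrainConfig) -> float:
    """Piecewise-linear warmup to lr0 over the first `warmup_epochs`
    epochs; afterwards constant lr0, or a cosine decay to 5% of lr0 when
    `cos_lr` is enabled."""
    warm = cfg.warmup_epochs * steps_per_epoch
    if step < warm:
        return cfg.lr0 * (step + 1) / warm
    if not cfg.cos_lr:
        return cfg.lr0
    total = cfg.epochs * steps_per_epoch
    frac = min(1.0, (step - warm) / max(1, total - warm))
    return cfg.lr0 * (0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * frac)))


class Trainer:
    def __init__(self, model: Detector, train_ds: StripDataset,
                 val_ds: StripDataset | None, cfg: TrainConfig):
        self.model = model
        self.train_ds = train_ds
        self.val_ds = val_ds
        self.cfg = cfg
        model.materialize()
        self.criterion = DetectionLoss(model.cfg.n_classes, model.cfg.reg_max)
        self.optimizer = SGD(model.parameters(), lr=cfg.lr0,
                             momentum=cfg.momentum,
                             weight_decay=cfg.weight_decay)
        self.history = []
        self.best_state = None
        self.best_map = -1.0

    def _mosaic_enabled(self, epoch: int) -> bool:
        """Mosaic is sampled only before the final `mosaic_off_last` epochs
        (epoch is 1-based)."""
        return epoch <= self.cfg.epochs - self.cfg.mosaic_off_last

    def _batch(self, idxs, rng, use_mosaic: bool):
        imgs, targets = [], []
        for i in idxs:
            if use_mosaic and rng.random() < self.cfg.mosaic_prob:
                picks = [self.train_ds.load(j)[:2] for j in
                         rng.integers(len(self.train_ds), size=4)]
                img, labels = mosaic4(picks)
            else:
                img, labels, _ = self.train_ds.load(i)
            img, labels = augment(img, labels, self.cfg, rng)
            h, w = img.shape[:2]
            boxes = [b.to_xyxy(w, h) for b in labels]
            classes = [b.class_id for b in labels]
            imgs.append(img.astype(np.float32).transpose(2, 0, 1) / 255.0)
            targets.append(dict(boxes=np.asarray(boxes, dtype=np.float64)
                                .reshape(-1, 4),
                                classes=np.asarray(classes, dtype=np.int64)))
        return np.stack(imgs), targets

    def run(self) -> dict:
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        n = len(self.train_ds)
        if n == 0:
            raise ValueError("empty training dataset")
        steps_per_epoch = max(1, n // cfg.batch)
        step = 0
        bad_epochs = 0
        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(n)
            use_mosaic = self._mosaic_enabled(epoch)
            self.model.train_mode(True)
            losses = []
            for b in range(steps_per_epoch):
                idxs = order[b * cfg.batch:(b + 1) * cfg.batch]
                x, targets = self._batch(idxs, rng, use_mosaic)
                self.optimizer.lr = lr_at(step, steps_per_epoch, cfg)
                out = self.model.forward(x)
                total, breakdown = self.criterion(out, targets)
                if not np.isfinite(total.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch} step {b}: "
                        f"{asdict(breakdown) if hasattr(breakdown, '__dict__') else breakdown}")
                self.optimizer.zero_grad()
                total.backward()
                self._clip_gradients()
                self.optimizer.step()
                losses.append(float(total.data))
                step += 1
            record = dict(epoch=epoch, loss=float(np.mean(losses)),
                          lr=self.optimizer.lr, mosaic=bool(use_mosaic))
            if self.val_ds is not None and len(self.val_ds):
                record["val_map50"] = self._val_map()
                if record["val_map50"] > self.best_map + 1e-9:
                    self.best_map = record["val_map50"]
                    self.best_state = self.model.state_dict()
                    bad_epochs = 0
                else:
                    bad_epochs += 1
            self.history.append(record)
            if self.val_ds is not None and bad_epochs >= cfg.patience:
                break
        if self.best_state is not None:
            self.model.load_state_dict(self.best_state)
        self.model.train_mode(False)
        return dict(history=self.history, best_map=self.best_map)

    def _clip_gradients(self):
        clip = self.cfg.grad_clip
        if not clip:
            return
        total = 0.0
        params = self.optimizer.params
        for p in params:
            if p.grad is not None:
                total += float((p.grad ** 2).sum())
        norm = np.sqrt(total)
        if norm > clip:
            scale = clip / (norm + 1e-12)
            for p in params:
                if p.grad is not None:
                    p.grad *= scale

    def _val_map(self) -> float:
        from .evaluation import average_precision
        dets, gts = collect_detections(self.model, self.val_ds,
                                       conf_thr=0.05, iou_thr=0.5)
        res = average_precision(dets, gts, iou_thr=0.5)
        return res["map"]


def train(model: Detector, data_dir, cfg: TrainConfig,
          out_dir=None) -> dict:
    """Train `model` on a generated dataset directory with train/val splits;
    optionally save the best checkpoint and a per-epoch CSV metric log."""
    train_ds = StripDataset(data_dir, "train")
    val_ds = StripDataset(data_dir, "val")
    trainer = Trainer(model, train_ds, val_ds if len(val_ds) else None, cfg)
    result = trainer.run()
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        save_checkpoint(model, os.path.join(out_dir, "best.npz"))
        with open(os.path.join(out_dir, "metrics.csv"), "w") as fh:
            keys = sorted({k for r in trainer.history for k in r})
            fh.write(",".join(keys) + "\n")
            for r in trainer.history:
                fh.write(",".join(str(r.get(k, "")) for k in keys) + "\n")
    return result


def save_checkpoint(model: Detector, path) -> None:
    state = model.state_dict()
    arrays = {f"p{k}": v for k, v in state.items()}
    arrays["__config__"] = np.frombuffer(
        yaml.safe_dump(asdict(model.cfg)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> Detector:
    data = np.load(path)
    cfg_raw = yaml.safe_load(bytes(data["__config__"]).decode())
    for key in ("widths", "depths", "s5_kernels"):
        cfg_raw[key] = tuple(cfg_raw[key])
    model = Detector(ModelConfig(**cfg_raw)).materialize()
    state = {}
    for k in data.files:
        if not k.startswith("p"):
            continue
        key = k[1:]
        state[int(key) if key.isdigit() else key] = data[k]
    model.load_state_dict(state)
    model.train_mode(False)
    return model


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> list:
    """Greedy non-maximum suppression; returns kept indices, descending
    score order."""
    order = np.argsort(-scores)
    keep = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        ious = iou_xyxy(np.broadcast_to(boxes[i], (rest.size, 4)), boxes[rest])
        order = rest[ious <= iou_thr]
    return keep


def detect(model: Detector, image: np.ndarray, conf_thr: float = 0.25,
           iou_thr: float = 0.5, agnostic: bool = False) -> list:
    """Decode + per-class NMS.  `image` is (H, W, 3) uint8.

    Each anchor commits to its best class; suppression then runs per
    class (or across classes with `agnostic=True`, which treats
    overlapping boxes of different classes as duplicates).  Detections
    come back sorted by descending confidence."""
    if not 0 <= conf_thr <= 1 or not 0 <= iou_thr <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    model.train_mode(False)
    x = image.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
    out = model.forward(x)
    cls_list, reg_list, shapes = [], [], {}
    reg_max = model.cfg.reg_max
    for stride in sorted(out):
        cls_map, reg_map = out[stride]
        _, nc, h, w = cls_map.shape
        shapes[stride] = (h, w)
        cls_list.append(cls_map.data.reshape(nc, h * w).T)
        reg_list.append(reg_map.data.reshape(4, reg_max, h * w)
                        .transpose(2, 0, 1))
    scores = 1.0 / (1.0 + np.exp(-np.clip(np.concatenate(cls_list), -80, 80)))
    probs = _softmax_np(np.concatenate(reg_list), axis=-1)
    anchor_points, strides = make_anchors(shapes)
    boxes = decode_boxes(probs, anchor_points, strides)
    h_img, w_img = image.shape[:2]
    boxes[:, [0, 2]] = boxes[:, [0, 2]].clip(0, w_img)
    boxes[:, [1, 3]] = boxes[:, [1, 3]].clip(0, h_img)

    best_cls = scores.argmax(axis=1)
    best_conf = scores[np.arange(scores.shape[0]), best_cls]
    detections = []
    class_groups = ([None] if agnostic else range(scores.shape[1]))
    for cls in class_groups:
        mask = best_conf >= conf_thr
        if cls is not None:
            mask &= best_cls == cls
        if conf_thr >= 1.0 or not mask.any():
            continue
        cb, cs, cc = boxes[mask], best_conf[mask], best_cls[mask]
        valid = (cb[:, 2] - cb[:, 0] > 1) & (cb[:, 3] - cb[:, 1] > 1)
        cb, cs, cc = cb[valid], cs[valid], cc[valid]
        if not len(cb):
            continue
        for i in nms(cb, cs, iou_thr):
            detections.append(Detection(tuple(cb[i]), int(cc[i]),
                                        float(cs[i])))
    detections.sort(key=lambda d: -d.confidence)
    return detections


def predict_concentration(dets, binning: ConcentrationBinning) -> tuple:
    """Concentration readout from detections.

    No C-line -> (None, False): the assay is invalid.  C-line without a
    T-line -> (0.0, True): a valid negative.  Otherwise the representative
    concentration of the highest-confidence T-line class.
    """
    has_c = any(d.class_id == C_LINE_CLASS for d in dets)
    if not has_c:
        return None, False
    t_dets = [d for d in dets if d.class_id != C_LINE_CLASS]
    if not t_dets:
        return 0.0, True
    best = max(t_dets, key=lambda d: d.confidence)
    return float(binning.representative[best.class_id - 1]), True


def refine_concentration(image: np.ndarray, dets, law: ChromogenicLaw,
                         binning: ConcentrationBinning) -> tuple:
    """Optional sub-bin readout: invert the chromogenic law from the
    measured T-line darkness relative to the C-line.

    Darkness is estimated per band as the contrast between the band's mean
    colour and the nearby membrane along the band-colour axis; the law
    i(c) = i_max c / (k_half + c) is inverted as c = k_half i/(i_max - i).
    Off by default in the readout path.
    """
    conc, valid = predict_concentration(dets, binning)
    if not valid or conc == 0.0:
        return conc, valid
    t_best = max((d for d in dets if d.class_id != C_LINE_CLASS),
                 key=lambda d: d.confidence)
    c_best = max((d for d in dets if d.class_id == C_LINE_CLASS),
                 key=lambda d: d.confidence)
    d_t = _measured_darkness(image, t_best.box)
    d_c = _measured_darkness(image, c_best.box)
    if d_c <= 1e-6:
        return conc, valid
    # C-line renders at the law's fixed darkness: use it as the per-image
    # photometric scale
    i_t = np.clip(d_t / d_c * law.c_line_intensity, 0.0, 0.999 * law.i_max)
    c_hat = law.k_half * i_t / (law.i_max - i_t)
    lo, hi = binning.edges[0], binning.edges[-1]
    return float(np.clip(c_hat, lo, hi)), True


def _measured_darkness(image: np.ndarray, box) -> float:
    x1, y1, x2, y2 = [int(round(v)) for v in box]
    band = image[y1:y2, x1:x2].astype(np.float64)
    if band.size == 0:
        return 0.0
    h = y2 - y1
    above = image[max(0, y1 - 2 * h):y1, x1:x2].astype(np.float64)
    ref = above.reshape(-1, 3).mean(axis=0) if above.size else _MEMBRANE
    axis = _MEMBRANE - _BAND_FULL
    axis = axis / np.linalg.norm(axis)
    proj = (ref - band.reshape(-1, 3).mean(axis=0)) @ axis
    return float(max(proj, 0.0) / np.linalg.norm(_MEMBRANE - _BAND_FULL))


def collect_detections(model: Detector, ds: StripDataset,
                       conf_thr: float = 0.25, iou_thr: float = 0.5):
    """Run detection over a dataset; returns (detections, ground truths)
    in the evaluation module's record format."""
    dets, gts = [], []
    for i in range(len(ds)):
        img, labels, entry = ds.load(i)
        h, w = img.shape[:2]
        for b in labels:
            gts.append(dict(image_id=i, class_id=b.class_id,
                            box=b.to_xyxy(w, h)))
        for d in detect(model, img, conf_thr, iou_thr):
            dets.append(dict(image_id=i, class_id=d.class_id,
                             conf=d.confidence, box=d.box))
    return dets, gts
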