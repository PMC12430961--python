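"""Detection and quantification metrics.

Detection: greedy confidence-descending matching at an IoU threshold,
all-point-interpolated average precision per class, mAP@0.5 and
mAP@0.5:0.95, precision/recall/F1 at a fixed confidence, and a strip-level
confusion matrix built from the concentration readout.

Quantification: MAE/MSE/R^2/Pearson r on predicted vs. true concentration
and sensitivity/specificity/PPV/NPV after dichotomizing at clinical
thresholds (default 25/50/100 IU/L).  Undefined ratios are reported as
None together with the 2x2 counts, never coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .head_loss import iou_xyxy

__all__ = [
    "EvalReport", "QuantReport", "average_precision", "evaluate_detections",
    "regression_metrics", "threshold_diagnostics", "strip_confusion",
    "run_ablation", "ABLATION_ORDER",
]

ABLATION_ORDER = ("C-FPN", "LIVT", "S-5", "SimAM")


@dataclass
class EvalReport:
    precision: float
    recall: float
    f1: float
    map50: float
    map5095: float
    per_class_ap: dict
    confusion_matrix: np.ndarray = None


@dataclass
class QuantReport:
    mae: float
    mse: float
    r2: float
    pearson_r: float
    thresholds: dict = field(default_factory=dict)


def _ap_from_pr(recalls: np.ndarray, precisions: np.ndarray) -> float:
    """All-point interpolation: area under the precision envelope."""
    r = np.concatenate([[0.0], recalls, [recalls[-1] if recalls.size else 0.0]])
    p = np.concatenate([[1.0], precisions, [0.0]])
    # precision envelope: p(r) = max precision at recall >= r
    for i in range(p.size - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.nonzero(np.diff(r) > 0)[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def _match_class(dets, gts, iou_thr):
    """Greedy matching for one class: detections in descending confidence,
    each may claim the unmatched ground truth with highest IoU >= thr."""
    dets = sorted(dets, key=lambda d: (-d["conf"], d.get("order", 0)))
    gt_by_img = {}
    for k, g in enumerate(gts):
        gt_by_img.setdefault(g["image_id"], []).append(k)
    used = set()
    flags = []          # True = TP
    for d in dets:
        best_iou, best_k = 0.0, None
        for k in gt_by_img.get(d["image_id"], []):
            if k in used:
                continue
            iou = float(iou_xyxy(np.asarray(d["box"], dtype=np.float64),
                                 np.asarray(gts[k]["box"], dtype=np.float64)))
            if iou > best_iou:
                best_iou, best_k = iou, k
        if best_k is not None and best_iou >= iou_thr:
            used.add(best_k)
            flags.append(True)
        else:
            flags.append(False)
    return dets, np.asarray(flags, dtype=bool)


def average_precision(dets: list, gts: list, iou_thr: float = 0.5) -> dict:
    """Per-class AP with PR points and their mean.

    `dets`: dicts with image_id, class_id, conf, box (pixel corners);
    `gts`: dicts with image_id, class_id, box.  A class with ground truths
    but no detections scores AP 0; detections for a class with no ground
    truth also score AP 0 for that class.
    """
    classes = sorted({g["class_id"] for g in gts}
                     | {d["class_id"] for d in dets})
    per_class, pr_curves = {}, {}
    for cls in classes:
        cd = [d for d in dets if d["class_id"] == cls]
        cg = [g for g in gts if g["class_id"] == cls]
        if not cg:
            per_class[cls] = 0.0
            pr_curves[cls] = (np.zeros(0), np.zeros(0))
            continue
        if not cd:
            per_class[cls] = 0.0
            pr_curves[cls] = (np.zeros(0), np.zeros(0))
            continue
        _, flags = _match_class(cd, cg, iou_thr)
        tp = np.cumsum(flags)
        fp = np.cumsum(~flags)
        recalls = tp / len(cg)
        precisions = tp / np.maximum(tp + fp, 1)
        per_class[cls] = _ap_from_pr(recalls, precisions)
        pr_curves[cls] = (recalls, precisions)
    mean_ap = float(np.mean(list(per_class.values()))) if per_class else 0.0
    return dict(map=mean_ap, per_class=per_class, pr_curves=pr_curves)


def evaluate_detections(dets: list, gts: list, conf_thr: float = 0.25,
                        iou_thrs=None) -> EvalReport:
    """Headline detection report: mAP@0.5, mAP@0.5:0.95, and P/R/F1 of the
    detections above `conf_thr` under greedy matching at IoU 0.5."""
    iou_thrs = iou_thrs or [0.5 + 0.05 * i for i in range(10)]
    ap50 = average_precision(dets, gts, 0.5)
    maps = [average_precision(dets, gts, t)["map"] for t in iou_thrs]
    strong = [d for d in dets if d["conf"] >= conf_thr]
    tp = 0
    for cls in {g["class_id"] for g in gts}:
        cd = [d for d in strong if d["class_id"] == cls]
        cg = [g for g in gts if g["class_id"] == cls]
        if cd and cg:
            _, flags = _match_class(cd, cg, 0.5)
            tp += int(flags.sum())
    n_det, n_gt = len(strong), len(gts)
    precision = tp / n_det if n_det else 0.0
    recall = tp / n_gt if n_gt else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return EvalReport(precision=precision, recall=recall, f1=f1,
                      map50=ap50["map"], map5095=float(np.mean(maps)),
                      per_class_ap=ap50["per_class"])


def regression_metrics(pred, true) -> dict:
    """MAE, MSE, R^2 = 1 - SSres/SStot and Pearson r.

    A zero-variance truth vector leaves R^2 (and r) as None — flagged,
    not silently zeroed.
    """
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(true, dtype=np.float64)
    if p.size == 0 or p.shape != t.shape:
        raise ValueError("pred/true must be equal-length nonempty vectors")
    err = p - t
    mae = float(np.abs(err).mean())
    mse = float((err ** 2).mean())
    sstot = float(((t - t.mean()) ** 2).sum())
    if sstot == 0.0:
        return dict(mae=mae, mse=mse, r2=None, pearson_r=None,
                    note="zero variance in truth")
    r2 = 1.0 - float((err ** 2).sum()) / sstot
    sp = p.std()
    pearson = (float(np.corrcoef(p, t)[0, 1]) if sp > 0 else None)
    return dict(mae=mae, mse=mse, r2=r2, pearson_r=pearson)


def threshold_diagnostics(pred, true, thresholds=(25.0, 50.0, 100.0)) -> dict:
    """Dichotomize both vectors at each threshold (positive = >= t) and
    report sensitivity, specificity, PPV, NPV with the 2x2 counts."""
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(true, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty vectors")
    out = {}
    for thr in thresholds:
        pp, tt = p >= thr, t >= thr
        tp = int(np.sum(pp & tt))
        fp = int(np.sum(pp & ~tt))
        tn = int(np.sum(~pp & ~tt))
        fn = int(np.sum(~pp & tt))

        def rate(num, den):
            return num / den if den else None

        out[float(thr)] = dict(
            tp=tp, fp=fp, tn=tn, fn=fn,
            sensitivity=rate(tp, tp + fn), specificity=rate(tn, tn + fp),
            ppv=rate(tp, tp + fp), npv=rate(tn, tn + fn))
    return out


def strip_confusion(pred_classes, true_classes, n_bins: int) -> np.ndarray:
    """Strip-level confusion matrix over {negative, bin 0..n_bins-1,
    invalid}: rows = truth, columns = prediction.  Class coding:
    -1 negative, 0..n_bins-1 positive bins, None invalid."""
    size = n_bins + 2          # negative + bins + invalid column
    cm = np.zeros((n_bins + 1, size), dtype=np.int64)

    def row(c):
        return 0 if c == -1 else 1 + int(c)

    def col(c):
        if c is None:
            return size - 1
        return 0 if c == -1 else 1 + int(c)

    for pc, tc in zip(pred_classes, true_classes):
        cm[row(tc), col(pc)] += 1
    return cm


def run_ablation(base_model_cfg, data_dir, train_cfg,
                 toggles=ABLATION_ORDER) -> dict:
    """Cumulative ablation: baseline, then each toggle added in order,
    trained and evaluated on the same seeded splits.

    Returns rows of (name, map50, map5095, precision, recall) and a
    markdown table.  LIVT without C-FPN is rejected, matching the
    cumulative design.
    """
    from dataclasses import replace
    from .model import Detector
    from .pipeline import Trainer, StripDataset, collect_detections

    bad = set(toggles) - set(ABLATION_ORDER)
    if bad:
        raise ValueError(f"unknown toggles: {sorted(bad)}")
    toggles = [t for t in ABLATION_ORDER if t in toggles]
    if "LIVT" in toggles and "C-FPN" not in toggles:
        raise ValueError("LIVT requires the cross-FPN neck (C-FPN)")

    flag_map = {"C-FPN": "use_cfpn", "LIVT": "use_livt",
                "S-5": "use_s5", "SimAM": "use_simam"}
    variants = [("baseline", [])]
    for i in range(len(toggles)):
        active = toggles[:i + 1]
        variants.append(("+".join(["baseline"] + active), active))

    rows = []
    for name, active in variants:
        flags = {v: False for v in flag_map.values()}
        for t in active:
            flags[flag_map[t]] = True
        cfg = replace(base_model_cfg, **flags)
        model = Detector(cfg)
        train_ds = StripDataset(data_dir, "train")
        val_ds = StripDataset(data_dir, "val")
        trainer = Trainer(model, train_ds, val_ds, train_cfg)
        trainer.run()
        dets, gts = collect_detections(model, val_ds, conf_thr=0.05)
        report = evaluate_detections(dets, gts)
        rows.append(dict(model=name, map50=report.map50,
                         map5095=report.map5095,
                         precision=report.precision, recall=report.recall))

    lines = ["| Model | mAP@0.5 | mAP@0.5:0.95 | Precision | Recall |",
             "|---|---|---|---|---|"]
    for r in rows:
        lines.append(f"| {r['model']} | {r['map50']:.3f} | {r['map5095']:.3f} "
                     f"| {r['precision']:.3f} | {r['recall']:.3f} |")
    return dict(rows=rows, markdown="\n".join(lines))
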