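"""Instance-level detection/segmentation evaluation.

Mask IoU, greedy confidence-ordered matching, precision/recall/F1,
per-class average precision with 101-point interpolation, mAP@0.5 and
mAP@0.5:0.95 (IoU thresholds 0.50 to 0.95 in steps of 0.05), and the
precision-recall and F1-confidence curves used to pick an operating point.

Matching follows the COCO conventions the segmentation-model ecosystem
reports with: predictions are processed in descending confidence (ties
broken lexicographically by instance id for reproducibility) and each is
matched to the unmatched same-class ground-truth instance of highest
IoU >= threshold.  Ground-truth instances are independent even when their
masks overlap — two translucent cells sharing 40% of their pixels are each
matchable — and a GT is never discarded because it overlaps another GT.

True negatives are undefined for instance detection (there is no enumerable
set of "background instances") and are reported as not-applicable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation_io import InstanceMask

#: IoU thresholds of the mAP 50-95 convention.
MAP_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


# ---------------------------------------------------------------------------
# IoU
# ---------------------------------------------------------------------------


def mask_iou(a: InstanceMask, b: InstanceMask) -> float:
    """Intersection-over-union of two instance masks in one image frame."""
    area_a, area_b = a.area_px, b.area_px
    if area_a == 0 and area_b == 0:
        raise ValueError("IoU of two empty masks is undefined")
    ar0, ac0, ar1, ac1 = a.bbox
    br0, bc0, br1, bc1 = b.bbox
    r0, c0 = max(ar0, br0), max(ac0, bc0)
    r1, c1 = min(ar1, br1), min(ac1, bc1)
    if r1 <= r0 or c1 <= c0:
        return 0.0
    sub_a = a.grid[r0 - ar0:r1 - ar0, c0 - ac0:c1 - ac0]
    sub_b = b.grid[r0 - br0:r1 - br0, c0 - bc0:c1 - bc0]
    inter = int((sub_a & sub_b).sum())
    return inter / (area_a + area_b - inter)


def box_iou(a: InstanceMask, b: InstanceMask) -> float:
    """Bounding-box IoU (for detection-style curves)."""
    ar0, ac0, ar1, ac1 = a.bbox
    br0, bc0, br1, bc1 = b.bbox
    ih = max(0, min(ar1, br1) - max(ar0, br0))
    iw = max(0, min(ac1, bc1) - max(ac0, bc0))
    inter = ih * iw
    union = (ar1 - ar0) * (ac1 - ac0) + (br1 - br0) * (bc1 - bc0) - inter
    return inter / union if union else 0.0


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def _pred_sort_key(pred: InstanceMask):
    return (-(pred.confidence if pred.confidence is not None else 1.0),
            pred.instance_id or "")


@dataclass
class MatchResult:
    """Outcome of greedy prediction-to-ground-truth matching."""

    iou_threshold: float
    #: per prediction (in processing order): (pred_id, matched gt index or None)
    pred_matches: list[tuple[str, int | None]]
    gt_matched: list[bool]
    tp: int
    fp: int
    fn: int
    #: true negatives are undefined for instance detection
    tn: None = None


def match_instances(
    preds: list[InstanceMask],
    gts: list[InstanceMask],
    iou_threshold: float,
    class_aware: bool = True,
    iou_fn=mask_iou,
) -> MatchResult:
    """Greedily match predictions to ground truth at one IoU threshold.

    Each prediction (descending confidence) takes the unmatched ground-truth
    instance — of the same class when ``class_aware`` — with the highest
    IoU >= threshold; each GT is used at most once.
    """
    if not 0 < iou_threshold <= 1:
        raise ValueError("iou_threshold must be in (0, 1]")
    order = sorted(range(len(preds)), key=lambda i: _pred_sort_key(preds[i]))
    gt_matched = [False] * len(gts)
    pred_matches: list[tuple[str, int | None]] = []
    tp = 0
    for i in order:
        pred = preds[i]
        best_j, best_iou = None, 0.0
        for j, gt in enumerate(gts):
            if gt_matched[j]:
                continue
            if class_aware and gt.class_label != pred.class_label:
                continue
            iou = iou_fn(pred, gt)
            if iou >= iou_threshold and iou > best_iou:
                best_j, best_iou = j, iou
        if best_j is not None:
            gt_matched[best_j] = True
            tp += 1
        pred_matches.append((pred.instance_id or str(i), best_j))
    return MatchResult(
        iou_threshold=iou_threshold,
        pred_matches=pred_matches,
        gt_matched=gt_matched,
        tp=tp,
        fp=len(preds) - tp,
        fn=len(gts) - tp,
    )


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall: 2PR/(P+R), 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must be in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def precision_recall_f1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """P, R and F1 from match counts.

    P = TP/(TP+FP) (1.0 when no predictions), R = TP/(TP+FN) (1.0 when no
    ground truth), F1 = 2PR/(P+R) (0 when P+R = 0).
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp + fn == 0:
        raise ValueError("no predictions and no ground truth")
    p = tp / (tp + fp) if tp + fp else 1.0
    r = tp / (tp + fn) if tp + fn else 1.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


# ---------------------------------------------------------------------------
# Average precision
# ---------------------------------------------------------------------------


def average_precision(
    preds: list[InstanceMask],
    gts: list[InstanceMask],
    iou_threshold: float,
    interpolation: str = "coco101",
    iou_fn=mask_iou,
) -> tuple[float, list[tuple[float, float]]]:
    """AP at one IoU threshold, with the cumulative PR points.

    ``coco101``: precision at recall r is the maximum precision attained at
    any recall >= r, averaged over the 101 recall levels 0.00, 0.01, ... 1.00.
    ``continuous``: exact area under the same precision envelope.
    """
    if not gts:
        raise ValueError("undefined AP: no ground-truth instances")
    if interpolation not in ("coco101", "continuous"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    match = match_instances(preds, gts, iou_threshold, iou_fn=iou_fn)
    n_gt = len(gts)
    tp_flags = np.array([m is not None for _, m in match.pred_matches])
    if len(tp_flags) == 0:
        return 0.0, []
    cum_tp = np.cumsum(tp_flags)
    cum_fp = np.cumsum(~tp_flags)
    recall = cum_tp / n_gt
    precision = cum_tp / (cum_tp + cum_fp)
    pr_points = list(zip(recall.tolist(), precision.tolist()))

    # precision envelope: max precision at recall >= r
    env_p = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "coco101":
        grid = np.linspace(0.0, 1.0, 101)
        interp = np.zeros_like(grid)
        for k, r in enumerate(grid):
            idx = np.searchsorted(recall, r, side="left")
            interp[k] = env_p[idx] if idx < len(env_p) else 0.0
        ap = float(interp.mean())
    else:
        r_prev = 0.0
        ap = 0.0
        for i in range(len(recall)):
            if recall[i] > r_prev:
                ap += (recall[i] - r_prev) * env_p[i]
                r_prev = recall[i]
        ap = float(ap)
    return ap, pr_points


@dataclass
class APSummary:
    """Evaluation summary across classes and IoU thresholds."""

    per_class_ap: dict[str, dict[float, float]]
    map50: float
    map50_95: float
    pr_points: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    f1_curve: list[tuple[float, float]] = field(default_factory=list)
    best_confidence: float | None = None
    best_f1: float | None = None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "map50": self.map50,
            "map50_95": self.map50_95,
            "per_class_ap": {
                cls: {f"{t:.2f}": ap for t, ap in d.items()}
                for cls, d in self.per_class_ap.items()
            },
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "best_confidence": self.best_confidence,
            "best_f1": self.best_f1,
            "true_negatives": "not applicable for instance detection",
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def map_metrics(
    preds: list[InstanceMask],
    gts: list[InstanceMask],
    thresholds: tuple[float, ...] = MAP_THRESHOLDS,
    iou_fn=mask_iou,
) -> APSummary:
    """Per-class AP over the 0.50-0.95 threshold ladder, mAP50 and mAP50-95.

    Classes absent from the ground truth are excluded from the means.  Also
    fills pooled P/R/F1 at IoU 0.5 and the F1-confidence curve.
    """
    classes = sorted({g.class_label for g in gts})
    if not classes:
        raise ValueError("no ground-truth instances")
    per_class: dict[str, dict[float, float]] = {}
    pr_points: dict[str, list[tuple[float, float]]] = {}
    for cls in classes:
        cls_gts = [g for g in gts if g.class_label == cls]
        cls_preds = [p for p in preds if p.class_label == cls]
        per_class[cls] = {}
        for t in thresholds:
            ap, pts = average_precision(cls_preds, cls_gts, float(t), iou_fn=iou_fn)
            per_class[cls][float(t)] = ap
            if np.isclose(t, 0.5):
                pr_points[cls] = pts
    t0 = float(thresholds[0])
    map50 = float(np.mean([per_class[c][t0] for c in classes]))
    map50_95 = float(np.mean([ap for c in classes for ap in per_class[c].values()]))

    m = match_instances(preds, gts, t0, iou_fn=iou_fn)
    p, r, f1 = precision_recall_f1(m.tp, m.fp, m.fn)
    curve = f1_confidence_curve(preds, gts, t0, iou_fn=iou_fn)
    best = max(curve, key=lambda cf: cf[1]) if curve else (None, None)
    return APSummary(
        per_class_ap=per_class,
        map50=map50,
        map50_95=map50_95,
        pr_points=pr_points,
        f1_curve=curve,
        best_confidence=best[0],
        best_f1=best[1],
        precision=p,
        recall=r,
        f1=f1,
    )


def f1_confidence_curve(
    preds: list[InstanceMask],
    gts: list[InstanceMask],
    iou_threshold: float,
    grid: int = 101,
    iou_fn=mask_iou,
) -> list[tuple[float, float]]:
    """Pooled F1 as a function of the confidence cutoff.

    For each cutoff c in a uniform grid over [0, 1], predictions with
    confidence >= c are kept and the pooled (all-class) F1 computed.
    """
    curve = []
    for c in np.linspace(0.0, 1.0, grid):
        kept = [p for p in preds
                if (p.confidence if p.confidence is not None else 1.0) >= c]
        if not kept and not gts:
            curve.append((float(c), 0.0))
            continue
        m = match_instances(kept, gts, iou_threshold, iou_fn=iou_fn)
        if m.tp + m.fp + m.fn == 0:
            curve.append((float(c), 0.0))
            continue
        _, _, f1 = precision_recall_f1(m.tp, m.fp, m.fn)
        curve.append((float(c), f1))
    return curve


# ---------------------------------------------------------------------------
# Prediction ingestion
# ---------------------------------------------------------------------------


def load_predictions(mask_dir: str | Path, sidecar_csv: str | Path) -> list[InstanceMask]:
    """Load predicted masks plus their confidence sidecar.

    The sidecar CSV has columns ``instance_id, class, confidence``; each
    ``instance_id`` names a ``{instance_id}_{class}.png`` full-frame mask in
    ``mask_dir``.
    """
    import csv as _csv

    from .annotation_io import load_mask_png

    mask_dir = Path(mask_dir)
    preds = []
    with open(sidecar_csv, newline="") as fh:
        for row in _csv.DictReader(fh):
            iid = row["instance_id"]
            cls = row["class"]
            path = mask_dir / f"{iid}_{cls}.png"
            preds.append(
                load_mask_png(path, class_label=cls, instance_id=iid,
                              confidence=float(row["confidence"]))
            )
    return preds
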