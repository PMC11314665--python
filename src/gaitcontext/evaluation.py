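"""Detection evaluation: IoU, per-class AP at IoU 0.5, and mAP50.

Matching follows the convention of modern detector toolkits: within each
class, predictions are taken in descending confidence order (ties broken
by input order); each is matched to the unmatched ground-truth box of
highest IoU, and counts as a true positive iff that IoU is >= 0.5.  AP is
the area under the all-point interpolated precision-recall curve; mAP50
averages AP over the classes with at least one ground-truth instance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import AnnotationRecord
from .core import BoundingBox

IOU_THRESHOLD = 0.5


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes on half-open pixel areas."""
    inter = a.intersection(b)
    if inter is None:
        return 0.0
    ia = inter.area
    return ia / (a.area + b.area - ia)


@dataclass
class EvalResult:
    per_class_ap: dict[str, float]
    map50: float


def average_precision(
    recalls: np.ndarray, precisions: np.ndarray, interpolation: str = "all_points"
) -> float:
    """Area under an interpolated precision-recall curve.

    ``all_points``: precision envelope integrated over recall (the
    convention of COCO-style toolkits).  ``eleven_point``: mean of the
    interpolated precision at recalls 0, 0.1, ..., 1.0 (classic VOC2007).
    """
    if recalls.size == 0:
        return 0.0
    r = np.concatenate([[0.0], recalls, [recalls[-1]]])
    p = np.concatenate([[0.0], precisions, [0.0]])
    # monotone non-increasing precision envelope from the right
    p = np.maximum.accumulate(p[::-1])[::-1]
    if interpolation == "all_points":
        idx = np.where(r[1:] != r[:-1])[0]
        return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))
    elif interpolation == "eleven_point":
        pts = []
        for t in np.linspace(0.0, 1.0, 11):
            mask = r >= t
            pts.append(p[mask].max() if mask.any() else 0.0)
        return float(np.mean(pts))
    raise ValueError(f"unknown interpolation {interpolation!r}")


def evaluate_map50(
    predictions: list[AnnotationRecord],
    truth: list[AnnotationRecord],
    iou_threshold: float = IOU_THRESHOLD,
    interpolation: str = "all_points",
) -> EvalResult:
    """Evaluate predicted boxes against ground truth at IoU >= 0.5.

    Predictions must carry confidences.  Classes never seen in the truth
    are excluded from the mean (there is no recall to measure); classes
    with truth but no predictions score AP = 0.
    """
    for rec in predictions:
        if rec.boxes and rec.confidences is None:
            raise ValueError(f"prediction record {rec.image_id!r} lacks confidences")

    truth_by_class: dict[str, dict[str, list[BoundingBox]]] = {}
    n_truth: dict[str, int] = {}
    for rec in truth:
        for name, box in rec.boxes:
            truth_by_class.setdefault(name, {}).setdefault(rec.image_id, []).append(box)
            n_truth[name] = n_truth.get(name, 0) + 1

    preds_by_class: dict[str, list[tuple[float, int, str, BoundingBox]]] = {}
    order = 0
    for rec in predictions:
        confs = rec.confidences or []
        for (name, box), conf in zip(rec.boxes, confs):
            preds_by_class.setdefault(name, []).append((conf, order, rec.image_id, box))
            order += 1

    per_class_ap: dict[str, float] = {}
    for cls, total in n_truth.items():
        preds = sorted(preds_by_class.get(cls, []), key=lambda t: (-t[0], t[1]))
        gt = truth_by_class[cls]
        matched: dict[str, list[bool]] = {
            img: [False] * len(boxes) for img, boxes in gt.items()
        }
        tp = np.zeros(len(preds))
        fp = np.zeros(len(preds))
        for i, (_conf, _ord, img, box) in enumerate(preds):
            candidates = gt.get(img, [])
            best_iou, best_j = 0.0, -1
            for j, tbox in enumerate(candidates):
                v = iou(box, tbox)
                if v > best_iou:
                    best_iou, best_j = v, j
            if best_j >= 0 and best_iou >= iou_threshold and not matched[img][best_j]:
                matched[img][best_j] = True
                tp[i] = 1
            else:
                fp[i] = 1
        if len(preds) == 0:
            per_class_ap[cls] = 0.0
            continue
        cum_tp = np.cumsum(tp)
        cum_fp = np.cumsum(fp)
        recalls = cum_tp / total
        precisions = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
        per_class_ap[cls] = average_precision(recalls, precisions, interpolation)

    map50 = float(np.mean(list(per_class_ap.values()))) if per_class_ap else 0.0
    return EvalResult(per_class_ap=per_class_ap, map50=map50)
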