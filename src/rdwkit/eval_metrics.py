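"""Detection evaluation: greedy matching, precision/recall, AP and mAP.

The protocol is the standard one behind "mAP@0.5": detections are sorted by
descending confidence; each is matched to the highest-IoU not-yet-consumed
ground truth of the same class in the same image, and counts as a true
positive if that IoU clears the threshold, otherwise a false positive.
Sweeping the sorted detection list traces a precision-recall curve; average
precision is the area under its monotone (right-to-left maximum) envelope,
computed with all-point interpolation; mAP is the unweighted mean of
per-class AP over classes that have at least one ground truth:

    P = TP / (TP + FP),  R = TP / (TP + FN),
    AP = integral of P(R) dR,  mAP = (1/N) * sum_i AP_i.

Ties are deterministic: equal confidences keep input order (stable sort),
equal IoUs go to the earlier ground truth in list order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .boxes import BoxXYWH, read_yolo_labels
from .geometry_loss import iou

__all__ = [
    "Detection",
    "GroundTruth",
    "EvalReport",
    "match_detections",
    "precision_recall",
    "average_precision",
    "mean_average_precision",
    "mean_average_precision_range",
    "evaluate",
    "read_detections_jsonl",
    "write_detections_jsonl",
    "load_ground_truth_dir",
]


@dataclass(frozen=True)
class Detection:
    image_id: str
    class_id: int
    box: BoxXYWH
    confidence: float

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")


@dataclass(frozen=True)
class GroundTruth:
    image_id: str
    class_id: int
    box: BoxXYWH


@dataclass
class EvalReport:
    """Per-class AP plus precision/recall counts at one operating point."""

    per_class_ap: Dict[int, float]
    map50: float
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    map_range: Optional[float] = None  # mAP@0.5:0.95 when requested

    def to_dict(self) -> dict:
        d = {
            "per_class_ap": {str(k): v for k, v in sorted(self.per_class_ap.items())},
            "map50": self.map50,
            "precision": self.precision,
            "recall": self.recall,
            "counts": {"tp": self.tp, "fp": self.fp, "fn": self.fn},
        }
        if self.map_range is not None:
            d["map50_95"] = self.map_range
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def table(self) -> str:
        lines = [f"{'class':>8} {'AP':>8}"]
        for cls, ap in sorted(self.per_class_ap.items()):
            lines.append(f"{cls:>8d} {ap:>8.4f}")
        lines.append(f"{'mAP@0.5':>8} {self.map50:>8.4f}")
        if self.map_range is not None:
            lines.append(f"{'mAP@.5:.95':>10} {self.map_range:>6.4f}")
        lines.append(
            f"P={self.precision:.4f} R={self.recall:.4f} (TP={self.tp} FP={self.fp} FN={self.fn})"
        )
        return "\n".join(lines)


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruth],
    iou_threshold: float = 0.5,
) -> Tuple[List[bool], int]:
    """Greedy confidence-ordered matching.

    Returns per-detection TP flags (in the order of the confidence-sorted
    detection list — pair with :func:`sorted_detections` order) and the
    number of unmatched ground truths (FN).
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError(f"iou_threshold must be in (0,1), got {iou_threshold}")
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    consumed = [False] * len(gts)
    flags: List[bool] = []
    for i in order:
        d = dets[i]
        best_iou, best_j = 0.0, -1
        for j, g in enumerate(gts):
            if consumed[j] or g.image_id != d.image_id or g.class_id != d.class_id:
                continue
            ov = iou(d.box, g.box)
            if ov > best_iou:  # strict: IoU ties keep the earlier ground truth
                best_iou, best_j = ov, j
        if best_j >= 0 and best_iou >= iou_threshold:
            consumed[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    return flags, consumed.count(False)


def precision_recall(tp: int, fp: int, fn: int) -> Tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); the 0/0 case is defined as 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r


class UndefinedAPError(ValueError):
    """Raised when AP is requested for a class with no ground truth."""


def average_precision(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruth],
    class_id: int,
    iou_threshold: float = 0.5,
) -> float:
    """All-point interpolated AP for one class."""
    cls_gts = [g for g in gts if g.class_id == class_id]
    if not cls_gts:
        raise UndefinedAPError(f"no ground truth for class {class_id}")
    cls_dets = sorted(
        (d for d in dets if d.class_id == class_id), key=lambda d: -d.confidence
    )
    flags, _ = match_detections(cls_dets, cls_gts, iou_threshold)
    if not cls_dets:
        return 0.0
    tps = np.cumsum(np.asarray(flags, dtype=float))
    fps = np.cumsum(1.0 - np.asarray(flags, dtype=float))
    recall = tps / len(cls_gts)
    precision = tps / np.maximum(tps + fps, 1e-12)
    # monotone envelope + all-point interpolation
    r = np.concatenate([[0.0], recall, [1.0]])
    p = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.nonzero(r[1:] != r[:-1])[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def mean_average_precision(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruth],
    iou_threshold: float = 0.5,
) -> Tuple[float, Dict[int, float]]:
    """Unweighted mean of per-class AP over classes with ground truth."""
    classes = sorted({g.class_id for g in gts})
    if not classes:
        raise ValueError("cannot compute mAP without any ground truth")
    per_class = {c: average_precision(dets, gts, c, iou_threshold) for c in classes}
    return float(np.mean(list(per_class.values()))), per_class


def mean_average_precision_range(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruth],
    thresholds: Optional[Sequence[float]] = None,
) -> float:
    """mAP averaged over IoU thresholds 0.50:0.05:0.95 (the COCO-style headline)."""
    if thresholds is None:
        thresholds = np.arange(0.5, 0.96, 0.05)
    return float(np.mean([mean_average_precision(dets, gts, t)[0] for t in thresholds]))


def evaluate(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruth],
    iou_threshold: float = 0.5,
    conf_threshold: float = 0.0,
    with_range: bool = False,
) -> EvalReport:
    """Full report: per-class AP, mAP, and P/R at the given confidence floor."""
    map50, per_class = mean_average_precision(dets, gts, iou_threshold)
    op_dets = [d for d in dets if d.confidence >= conf_threshold]
    flags, fn = match_detections(op_dets, gts, iou_threshold)
    tp = sum(flags)
    fp = len(flags) - tp
    p, r = precision_recall(tp, fp, fn)
    return EvalReport(
        per_class_ap=per_class,
        map50=map50,
        precision=p,
        recall=r,
        tp=tp,
        fp=fp,
        fn=fn,
        map_range=mean_average_precision_range(dets, gts) if with_range else None,
    )


# ---------------------------------------------------------------------------
# I/O: detections as JSON lines, ground truth as YOLO label directories
# ---------------------------------------------------------------------------


def write_detections_jsonl(path: str | Path, dets: Iterable[Detection]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in dets:
            fh.write(
                json.dumps(
                    {
                        "image_id": d.image_id,
                        "class_id": d.class_id,
                        "cx": d.box.cx,
                        "cy": d.box.cy,
                        "w": d.box.w,
                        "h": d.box.h,
                        "confidence": d.confidence,
                    }
                )
                + "\n"
            )


def read_detections_jsonl(path: str | Path) -> List[Detection]:
    out: List[Detection] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            o = json.loads(line)
            out.append(
                Detection(
                    image_id=str(o["image_id"]),
                    class_id=int(o["class_id"]),
                    box=BoxXYWH(o["cx"], o["cy"], o["w"], o["h"]),
                    confidence=float(o["confidence"]),
                )
            )
    return out


def load_ground_truth_dir(labels_dir: str | Path) -> List[GroundTruth]:
    """Read every ``*.txt`` YOLO label file in a directory; image_id = stem."""
    labels_dir = Path(labels_dir)
    gts: List[GroundTruth] = []
    for path in sorted(labels_dir.glob("*.txt")):
        for cls, box in read_yolo_labels(path):
            gts.append(GroundTruth(image_id=path.stem, class_id=cls, box=box))
    return gts
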