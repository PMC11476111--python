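"""Detection metric suite.

Implements the full evaluation protocol for the detector: greedy
confidence-ordered matching of detections to ground truth at an IoU
threshold, precision/recall, the finite-difference area under the PR
staircase

    AP = sum_k (R_k - R_{k-1}) * P_k

(with an optional COCO-style 101-point interpolated mode), mAP over
classes, mAP averaged over IoU thresholds 0.50:0.95:0.05, size-stratified
AP with COCO area bands (32^2, 96^2), image-level detection rates
(P, DR, FPR, MR with MR = 1 - DR and FPR using empty shots as the
negative class), per-class confusion matrices, and the empty-shot
absence-detection rate used to audit camera-trap robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detector import Detection, iou_matrix

COCO_SMALL = 32**2
COCO_MEDIUM = 96**2
IOU_RANGE = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# matching

@dataclass
class MatchResult:
    """Per-detection TP/FP flags in confidence order, plus FN count."""

    scores: np.ndarray  # descending
    tp: np.ndarray  # bool per detection
    n_gt: int
    matched_gt: np.ndarray  # GT index per detection, -1 for FP

    @property
    def n_tp(self) -> int:
        return int(self.tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.tp).sum())

    @property
    def n_fn(self) -> int:
        return self.n_gt - self.n_tp


def match_detections(
    detections: list[Detection],
    gt_boxes: np.ndarray,
    gt_labels: np.ndarray,
    iou_threshold: float = 0.5,
    class_agnostic: bool = False,
) -> MatchResult:
    """Greedy one-to-one matching by descending confidence.

    Each detection is matched to the not-yet-matched ground-truth box of
    the same class (unless ``class_agnostic``) with the highest IoU at or
    above the threshold; everything else is a false positive, and
    unmatched ground truth counts as false negatives.
    """
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    gt_labels = np.asarray(gt_labels).reshape(-1)
    order = sorted(range(len(detections)), key=lambda i: -detections[i].score)
    scores = np.array([detections[i].score for i in order])
    tp = np.zeros(len(order), dtype=bool)
    matched_gt = np.full(len(order), -1, dtype=int)
    taken = np.zeros(len(gt_boxes), dtype=bool)
    if len(gt_boxes):
        ious = iou_matrix(
            np.array([detections[i].box for i in order]).reshape(-1, 4), gt_boxes
        )
    for k, i in enumerate(order):
        best, best_j = iou_threshold, -1
        for j in range(len(gt_boxes)):
            if taken[j]:
                continue
            if not class_agnostic and gt_labels[j] != detections[i].label:
                continue
            if ious[k, j] >= best:
                best, best_j = ious[k, j], j
        if best_j >= 0:
            tp[k] = True
            taken[best_j] = True
            matched_gt[k] = best_j
    return MatchResult(scores, tp, len(gt_boxes), matched_gt)


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float | None]:
    """Precision TP/(TP+FP) and recall TP/(TP+FN).

    With no detections precision is 1 by convention (nothing asserted,
    nothing wrong); recall is None when no ground truth exists.
    """
    if min(tp, fp, fn) < 0:
        raise EvaluationError("counts must be nonnegative")
    p = tp / (tp + fp) if (tp + fp) > 0 else 1.0
    r = tp / (tp + fn) if (tp + fn) > 0 else None
    return p, r


# ---------------------------------------------------------------------------
# PR curves and AP

@dataclass
class PRCurve:
    """Rank-indexed recall/precision points (R_0 = 0 implicit)."""

    recall: np.ndarray
    precision: np.ndarray
    n_gt: int = 0

    def __post_init__(self):
        self.recall = np.asarray(self.recall, dtype=np.float64).reshape(-1)
        self.precision = np.asarray(self.precision, dtype=np.float64).reshape(-1)
        if self.recall.shape != self.precision.shape:
            raise EvaluationError("recall and precision must align")


def pr_curve(scores: np.ndarray, tp: np.ndarray, n_gt: int) -> PRCurve:
    """PR staircase from confidence-ordered TP flags."""
    order = np.argsort(-np.asarray(scores))
    flags = np.asarray(tp, dtype=bool)[order]
    cum_tp = np.cumsum(flags)
    ranks = np.arange(1, len(flags) + 1)
    recall = cum_tp / n_gt if n_gt > 0 else np.zeros(len(flags))
    precision = cum_tp / ranks
    return PRCurve(recall, precision, n_gt)


def average_precision(pr: PRCurve, interpolated: bool = False) -> float:
    """Area under the PR staircase.

    Default: the literal finite-difference sum over ranks.  With
    ``interpolated=True``, the COCO 101-point rule (mean over recall grid
    of the max precision at recall >= r).
    """
    r, p = pr.recall, pr.precision
    if len(r) == 0:
        return 0.0
    if np.any(np.diff(r) < -1e-12):
        raise EvaluationError("recall must be nondecreasing")
    if interpolated:
        grid = np.linspace(0, 1, 101)
        # max precision at recall >= g, scanned from the right
        p_right = np.maximum.accumulate(p[::-1])[::-1]
        out = 0.0
        for g in grid:
            idx = np.searchsorted(r, g, side="left")
            out += p_right[idx] if idx < len(r) else 0.0
        return out / 101
    prev = 0.0
    ap = 0.0
    for rk, pk in zip(r, p):
        ap += (rk - prev) * pk
        prev = rk
    return float(ap)


def mean_ap(per_class_aps) -> float:
    """Arithmetic mean of per-class APs (dict or sequence)."""
    vals = list(per_class_aps.values()) if isinstance(per_class_aps, dict) else list(per_class_aps)
    vals = [v for v in vals if v is not None]
    if not vals:
        raise EvaluationError("no classes to average")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# dataset-level AP

def _class_pr(
    per_image_dets: list[list[Detection]],
    per_image_gt: list[tuple[np.ndarray, np.ndarray]],
    cls: int,
    iou_threshold: float,
) -> PRCurve:
    scores, flags = [], []
    n_gt = 0
    for dets, (gt_boxes, gt_labels) in zip(per_image_dets, per_image_gt):
        cls_dets = [d for d in dets if d.label == cls]
        mask = np.asarray(gt_labels).reshape(-1) == cls
        sub_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)[mask]
        n_gt += int(mask.sum())
        m = match_detections(cls_dets, sub_boxes, np.full(mask.sum(), cls), iou_threshold)
        scores.extend(m.scores.tolist())
        flags.extend(m.tp.tolist())
    return pr_curve(np.asarray(scores), np.asarray(flags, dtype=bool), n_gt)


def dataset_ap(
    per_image_dets,
    per_image_gt,
    classes,
    iou_threshold: float = 0.5,
    interpolated: bool = False,
) -> dict[int, float | None]:
    """Per-class AP over a test set; classes without ground truth map to None."""
    out = {}
    for cls in classes:
        curve = _class_pr(per_image_dets, per_image_gt, cls, iou_threshold)
        out[cls] = average_precision(curve, interpolated) if curve.n_gt > 0 else None
    return out


def map_range(
    per_image_dets,
    per_image_gt,
    classes,
    thresholds=IOU_RANGE,
    interpolated: bool = False,
) -> float:
    """mAP averaged over an IoU threshold range (default 0.50:0.95:0.05)."""
    maps = []
    for t in thresholds:
        aps = dataset_ap(per_image_dets, per_image_gt, classes, t, interpolated)
        maps.append(mean_ap(aps))
    return float(np.mean(maps))


def _box_area(box) -> float:
    return float((box[2] - box[0]) * (box[3] - box[1]))


def size_band(area: float) -> str:
    if area < COCO_SMALL:
        return "small"
    if area < COCO_MEDIUM:
        return "medium"
    return "large"


def size_stratified_ap(
    per_image_dets,
    per_image_gt,
    classes,
    iou_threshold: float = 0.5,
) -> dict[str, float | None]:
    """AP restricted to small/medium/large ground-truth area bands.

    A band with no ground truth anywhere reports None.  Detections are
    assigned to the band of their matched ground truth; unmatched
    detections count against the band of their own area.
    """
    out = {}
    for band in ("small", "medium", "large"):
        scores, flags = [], []
        n_gt = 0
        for dets, (gt_boxes, gt_labels) in zip(per_image_dets, per_image_gt):
            gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
            gt_labels = np.asarray(gt_labels).reshape(-1)
            in_band = np.array([size_band(_box_area(b)) == band for b in gt_boxes], dtype=bool)
            n_gt += int(in_band.sum())
            m = match_detections(list(dets), gt_boxes, gt_labels, iou_threshold)
            order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
            for k, i in enumerate(order):
                if m.tp[k]:
                    if in_band[m.matched_gt[k]]:
                        scores.append(m.scores[k])
                        flags.append(True)
                else:
                    if size_band(_box_area(dets[i].box)) == band:
                        scores.append(m.scores[k])
                        flags.append(False)
        if n_gt == 0:
            out[band] = None
            continue
        curve = pr_curve(np.asarray(scores), np.asarray(flags, dtype=bool), n_gt)
        out[band] = average_precision(curve)
    return out


# ---------------------------------------------------------------------------
# rates, confusion, absence

def detection_rates(
    matches: list[MatchResult],
    empty_image_detection_counts: list[int] | None = None,
) -> dict[str, float | None]:
    """Aggregate P, DR, FPR, MR over a test set.

    DR = TP/(TP+FN) and MR = 1 - DR exactly.  FPR is image-level: the
    fraction of empty images (the negative class) on which anything was
    detected; None when no empty images are supplied.
    """
    tp = sum(m.n_tp for m in matches)
    fp = sum(m.n_fp for m in matches)
    fn = sum(m.n_fn for m in matches)
    p, dr = precision_recall(tp, fp, fn)
    mr = None if dr is None else 1.0 - dr
    fpr = None
    if empty_image_detection_counts:
        n_fp_img = sum(1 for c in empty_image_detection_counts if c > 0)
        fpr = n_fp_img / len(empty_image_detection_counts)
    return {"P": p, "DR": dr, "FPR": fpr, "MR": mr}


def confusion_matrix(
    per_image_dets,
    per_image_gt,
    classes: list[int],
    iou_threshold: float = 0.5,
    normalize: bool = False,
) -> np.ndarray:
    """(C+1) x (C+1) matrix of true class (rows) vs predicted (columns).

    Matching is class-agnostic so cross-class confusions are visible; the
    extra row/column holds background (missed GT and spurious detections).
    With ``normalize=True`` each row with support is divided by its sum.
    """
    idx = {c: i for i, c in enumerate(classes)}
    C = len(classes)
    M = np.zeros((C + 1, C + 1))
    for dets, (gt_boxes, gt_labels) in zip(per_image_dets, per_image_gt):
        gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
        gt_labels = np.asarray(gt_labels).reshape(-1)
        m = match_detections(list(dets), gt_boxes, gt_labels, iou_threshold, class_agnostic=True)
        order = sorted(range(len(dets)), key=lambda i: -dets[i].score)
        seen_gt = set()
        for k, i in enumerate(order):
            if m.matched_gt[k] >= 0:
                true_c = idx[int(gt_labels[m.matched_gt[k]])]
                M[true_c, idx[dets[i].label]] += 1
                seen_gt.add(int(m.matched_gt[k]))
            else:
                M[C, idx[dets[i].label]] += 1
        for j, lab in enumerate(gt_labels):
            if j not in seen_gt:
                M[idx[int(lab)], C] += 1
    if normalize:
        sums = M.sum(axis=1, keepdims=True)
        M = np.divide(M, sums, out=np.zeros_like(M), where=sums > 0)
    return M


def absence_detection(empty_scenes, model, score_threshold: float | None = None) -> float:
    """Fraction of empty scenes on which the model fires no detection."""
    from .detector import detect

    scenes = [s for s in empty_scenes if s.n_targets == 0]
    if not scenes:
        raise EvaluationError("no empty scenes supplied")
    clean = sum(
        1 for s in scenes if len(detect(s.image, model, score_threshold)) == 0
    )
    return clean / len(scenes)


# ---------------------------------------------------------------------------
# end-to-end report

@dataclass
class EvalReport:
    per_class_ap: dict[int, float | None]
    mAP: float
    mAP_interpolated: float
    mAP_50_95: float
    ap_small: float | None
    ap_medium: float | None
    ap_large: float | None
    rates: dict[str, float | None]
    confusion: np.ndarray
    absence_rate: float | None
    classes: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_class_ap": {str(k): v for k, v in self.per_class_ap.items()},
            "mAP": self.mAP,
            "mAP_interpolated": self.mAP_interpolated,
            "mAP_50_95": self.mAP_50_95,
            "AP_small": self.ap_small,
            "AP_medium": self.ap_medium,
            "AP_large": self.ap_large,
            "rates": self.rates,
            "confusion": self.confusion.tolist(),
            "absence_rate": self.absence_rate,
            "classes": self.classes,
        }


def evaluate_detections(
    per_image_dets,
    scenes,
    classes: list[int] | None = None,
    iou_threshold: float = 0.5,
) -> EvalReport:
    """Score precomputed per-scene detections against scene ground truth."""
    per_image_gt = [(s.boxes, s.labels) for s in scenes]
    if classes is None:
        classes = sorted({int(l) for s in scenes for l in s.labels})
    if not classes:
        raise EvaluationError("no ground-truth classes present")
    aps = dataset_ap(per_image_dets, per_image_gt, classes, iou_threshold)
    aps_i = dataset_ap(per_image_dets, per_image_gt, classes, iou_threshold, interpolated=True)
    bands = size_stratified_ap(per_image_dets, per_image_gt, classes, iou_threshold)
    matches = [
        match_detections(list(d), s.boxes, s.labels, iou_threshold)
        for d, s in zip(per_image_dets, scenes)
    ]
    empties = [
        len(d) for d, s in zip(per_image_dets, scenes) if s.n_targets == 0
    ]
    rates = detection_rates(
        [m for m, s in zip(matches, scenes) if s.n_targets > 0],
        empties or None,
    )
    conf = confusion_matrix(per_image_dets, per_image_gt, classes, iou_threshold)
    absence = None
    if empties:
        absence = sum(1 for c in empties if c == 0) / len(empties)
    return EvalReport(
        per_class_ap=aps,
        mAP=mean_ap(aps),
        mAP_interpolated=mean_ap(aps_i),
        mAP_50_95=map_range(per_image_dets, per_image_gt, classes),
        ap_small=bands["small"],
        ap_medium=bands["medium"],
        ap_large=bands["large"],
        rates=rates,
        confusion=conf,
        absence_rate=absence,
        classes=classes,
    )


def evaluate_detector(model, scenes, iou_threshold: float = 0.5) -> EvalReport:
    """Run the detector over scenes and score it."""
    from .detector import detect

    dets = [detect(s.image, model) for s in scenes]
    classes = sorted({int(l) for s in scenes for l in s.labels}) or list(
        model.kb.species_ids
    )
    return evaluate_detections(dets, scenes, classes, iou_threshold)
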