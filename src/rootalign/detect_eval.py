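"""3D detection geometry and COCO-style evaluation.

Implements volumetric IoU between axis-aligned boxes, confidence-thresholded
non-maximum suppression, greedy confidence-ordered matching, precision /
recall / F1, and average precision with the 101-point interpolated
precision-recall integral (monotone envelope), averaged over IoU thresholds
0.50:0.05:0.95 for the mAP50-95 summary. A naive intensity-threshold
baseline detector is included so the full pipeline runs without any trained
network weights.

All evaluation here is single-class (one anatomical target), so mAP reduces
to AP; the API still carries labels for forward compatibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ContractViolationError, UndefinedAPError
from .io_formats import Box3D, Detection, Volume, voxel_to_world

__all__ = [
    "MatchCounts",
    "EvalReport",
    "DetectorConfig",
    "iou3d",
    "nms",
    "match_detections",
    "precision_recall_f1",
    "average_precision",
    "map_range",
    "evaluate",
    "baseline_detector",
]

COCO_IOU_THRESHOLDS = tuple(round(0.50 + 0.05 * k, 2) for k in range(10))
_RECALL_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass
class EvalReport:
    """Detection metrics at an operating point plus threshold-swept AP."""

    precision: float
    recall: float
    f1: float
    ap_per_iou: dict[float, float]
    map50: float
    map50_95: float
    per_image_iou: dict[str, float]
    counts: MatchCounts
    degenerate: bool = False  # a 0/0 precision or recall was reported as 0

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "ap_per_iou": {f"{t:.2f}": v for t, v in self.ap_per_iou.items()},
            "map50": self.map50,
            "map50_95": self.map50_95,
            "per_image_iou": dict(self.per_image_iou),
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp, "fn": self.counts.fn},
            "degenerate": self.degenerate,
        }


def iou3d(a: Box3D, b: Box3D) -> float:
    """Intersection over union of two axis-aligned 3D boxes.

    Intersection is the product of per-axis overlaps; union is
    ``vol(a) + vol(b) - intersection``.
    """
    if a.space != b.space:
        raise ContractViolationError(
            f"boxes are in different spaces ({a.space} vs {b.space})"
        )
    inter = float(np.prod(np.maximum(0.0, np.minimum(a.hi, b.hi) - np.maximum(a.lo, b.lo))))
    union = a.volume + b.volume - inter
    return inter / union


def nms(
    dets: list[Detection],
    conf_threshold: float = 0.5,
    iou_threshold: float = 0.5,
) -> list[Detection]:
    """Confidence-thresholded greedy non-maximum suppression.

    Detections below ``conf_threshold`` are dropped; then the
    highest-confidence survivor is kept and all same-label detections with
    IoU >= ``iou_threshold`` against it are suppressed, repeating until no
    detections remain. Confidence ties are broken by input order (stable),
    making the result deterministic.
    """
    candidates = [d for d in dets if d.confidence >= conf_threshold]
    order = sorted(range(len(candidates)), key=lambda i: (-candidates[i].confidence, i))
    kept: list[Detection] = []
    suppressed = set()
    for i in order:
        if i in suppressed:
            continue
        keeper = candidates[i]
        kept.append(keeper)
        for j in order:
            if j == i or j in suppressed:
                continue
            other = candidates[j]
            if other.label == keeper.label and iou3d(keeper.box, other.box) >= iou_threshold:
                suppressed.add(j)
    return kept


def match_detections(
    dets: list[Detection],
    gts: list[Box3D],
    iou_threshold: float,
) -> tuple[MatchCounts, list[float]]:
    """Greedy COCO matching of detections to ground truths in one image.

    Detections are taken in descending confidence; each matches the not-yet-
    matched ground truth of highest IoU provided it reaches the threshold.
    Returns the TP/FP/FN counts and, per ground truth, the IoU of its matched
    detection (0 when unmatched).
    """
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    matched_iou = [0.0] * len(gts)
    taken = [False] * len(gts)
    tp = fp = 0
    for i in order:
        det = dets[i]
        best_j, best_iou = -1, 0.0
        for j, gt in enumerate(gts):
            if taken[j]:
                continue
            iou = iou3d(det.box, gt)
            if iou > best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[best_j] = True
            matched_iou[best_j] = best_iou
            tp += 1
        else:
            fp += 1
    fn = len(gts) - tp
    return MatchCounts(tp=tp, fp=fp, fn=fn), matched_iou


def precision_recall_f1(counts: MatchCounts) -> tuple[float, float, float, bool]:
    """Precision, recall and F1 from match counts.

    A 0/0 ratio is reported as 0 with the returned ``degenerate`` flag set
    (and a warning), rather than raising.
    """
    degenerate = False
    if counts.tp + counts.fp > 0:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        precision, degenerate = 0.0, True
    if counts.tp + counts.fn > 0:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        recall, degenerate = 0.0, True
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    if degenerate:
        warnings.warn("0/0 in precision or recall reported as 0", stacklevel=2)
    return precision, recall, f1, degenerate


def _flatten(dets_by_image: dict[str, list[Detection]]) -> list[tuple[str, int, Detection]]:
    flat = [
        (image_id, k, det)
        for image_id, dets in dets_by_image.items()
        for k, det in enumerate(dets)
    ]
    # global descending-confidence sweep; stable within an image
    flat.sort(key=lambda t: (-t[2].confidence, t[0], t[1]))
    return flat


def average_precision(
    dets_by_image: dict[str, list[Detection]],
    gts_by_image: dict[str, list[Box3D]],
    iou_threshold: float,
    interpolation: str = "coco101",
) -> float:
    """COCO-style average precision at one IoU threshold.

    Detections across all images are swept by descending confidence; each
    is a TP if it matches a not-yet-matched ground truth in its image at
    IoU >= threshold, else an FP. The precision-recall curve gets the
    monotone (non-increasing) precision envelope and is read out at the 101
    recall points 0, 0.01, ..., 1.00 (``interpolation="coco101"``) or
    integrated exactly over all recall breakpoints
    (``interpolation="voc_all_points"``).
    """
    n_gt = sum(len(g) for g in gts_by_image.values())
    if n_gt == 0:
        raise UndefinedAPError("no ground-truth boxes; AP is undefined")

    taken = {image_id: [False] * len(g) for image_id, g in gts_by_image.items()}
    tps: list[bool] = []
    for image_id, _, det in _flatten(dets_by_image):
        gts = gts_by_image.get(image_id, [])
        best_j, best_iou = -1, 0.0
        for j, gt in enumerate(gts):
            if taken[image_id][j]:
                continue
            iou = iou3d(det.box, gt)
            if iou > best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[image_id][best_j] = True
            tps.append(True)
        else:
            tps.append(False)

    if not tps:
        return 0.0
    tp_cum = np.cumsum(tps)
    fp_cum = np.cumsum([not t for t in tps])
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # monotone envelope: precision at recall r is max precision at recall >= r
    envelope = np.maximum.accumulate(precision[::-1])[::-1]

    if interpolation == "coco101":
        idx = np.searchsorted(recall, _RECALL_GRID, side="left")
        interpolated = np.where(idx < len(envelope), envelope[np.minimum(idx, len(envelope) - 1)], 0.0)
        return float(interpolated.mean())
    if interpolation == "voc_all_points":
        r = np.concatenate([[0.0], recall])
        return float(np.sum((r[1:] - r[:-1]) * envelope))
    raise ContractViolationError(f"unknown interpolation mode {interpolation!r}")


def map_range(
    dets_by_image: dict[str, list[Detection]],
    gts_by_image: dict[str, list[Box3D]],
    thresholds: tuple[float, ...] = COCO_IOU_THRESHOLDS,
    interpolation: str = "coco101",
) -> tuple[float, float, dict[float, float]]:
    """AP at each IoU threshold; returns (mAP50, mAP50-95, per-threshold AP)."""
    ap_per_iou = {
        t: average_precision(dets_by_image, gts_by_image, t, interpolation=interpolation)
        for t in thresholds
    }
    map50 = ap_per_iou.get(0.5, ap_per_iou[min(ap_per_iou)])
    map50_95 = float(np.mean(list(ap_per_iou.values())))
    return map50, map50_95, ap_per_iou


def evaluate(
    dets_by_image: dict[str, list[Detection]],
    gts_by_image: dict[str, list[Box3D]],
    iou_threshold: float = 0.5,
    interpolation: str = "coco101",
) -> EvalReport:
    """Full detection report: operating-point metrics plus the AP sweep.

    ``per_image_iou`` records each image's best matched ground-truth IoU at
    the operating threshold (0 where nothing matched).
    """
    total = MatchCounts()
    per_image_iou: dict[str, float] = {}
    for image_id, gts in gts_by_image.items():
        counts, matched = match_detections(dets_by_image.get(image_id, []), gts, iou_threshold)
        total = total + counts
        per_image_iou[image_id] = max(matched) if matched else 0.0
    precision, recall, f1, degenerate = precision_recall_f1(total)
    map50, map50_95, ap_per_iou = map_range(
        dets_by_image, gts_by_image, interpolation=interpolation
    )
    return EvalReport(
        precision=precision,
        recall=recall,
        f1=f1,
        ap_per_iou=ap_per_iou,
        map50=map50,
        map50_95=map50_95,
        per_image_iou=per_image_iou,
        counts=total,
        degenerate=degenerate,
    )


@dataclass
class DetectorConfig:
    """Tunables of the naive baseline detector.

    threshold_hu
        Foreground threshold; contrast-filled structures exceed it.
    min_voxels
        Components smaller than this are ignored as specks.
    output_space
        ``"voxel"`` or ``"world"`` for the emitted boxes.
    """

    threshold_hu: float = 200.0
    min_voxels: int = 50
    connectivity: int = 26
    output_space: str = "voxel"


def baseline_detector(vol: Volume, config: DetectorConfig | None = None) -> list[Detection]:
    """Threshold-and-label stand-in for a trained 3D detector.

    The whole volume is thresholded, connected components are extracted, and
    each component's bounding box becomes a detection. Components are scored
    by voxel count times the isotropy ratio of their bounding box (smallest
    extent over largest), which favors large compact structures like a
    contrast-filled root over thin bright streaks; confidences are the
    scores normalized by the maximum, so the best candidate has
    confidence 1.
    """
    config = config or DetectorConfig()
    if vol.intensity_space != "hu":
        raise ContractViolationError("baseline_detector expects a volume in HU")
    fg = vol.data >= config.threshold_hu
    if not fg.any():
        return []
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[config.connectivity])
    labels, n = ndimage.label(fg, structure=structure)
    slices = ndimage.find_objects(labels)
    counts = np.bincount(labels.ravel())

    raw: list[tuple[float, Box3D]] = []
    for comp_id, slc in enumerate(slices, start=1):
        count = int(counts[comp_id])
        if count < config.min_voxels:
            continue
        lo = np.array([s.start for s in slc], dtype=float)
        hi = np.array([s.stop for s in slc], dtype=float)
        extents = hi - lo
        isotropy = float(extents.min() / extents.max())
        raw.append((count * isotropy, Box3D(lo=lo, hi=hi, space="voxel")))
    if not raw:
        return []
    top = max(score for score, _ in raw)
    raw.sort(key=lambda t: -t[0])
    dets = []
    for score, box in raw:
        if config.output_space == "world":
            box = voxel_to_world(box, vol.affine)
        dets.append(Detection(box=box, confidence=score / top))
    return dets
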