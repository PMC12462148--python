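"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (voxel enumeration, BFS flood fill,
per-prefix recomputation) and shares no code with the package, so agreement
between the two routes is meaningful.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def voxel_count_iou(lo_a, hi_a, lo_b, hi_b, grid: int) -> float:
    """IoU of two integer-corner half-open boxes by filling boolean grids."""
    ga = np.zeros((grid, grid, grid), dtype=bool)
    gb = np.zeros((grid, grid, grid), dtype=bool)
    ga[lo_a[0]:hi_a[0], lo_a[1]:hi_a[1], lo_a[2]:hi_a[2]] = True
    gb[lo_b[0]:hi_b[0], lo_b[1]:hi_b[1], lo_b[2]:hi_b[2]] = True
    inter = np.sum(ga & gb)
    union = np.sum(ga | gb)
    return inter / union


def _neighbor_offsets(connectivity: int):
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                manhattan = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                offsets.append((dx, dy, dz))
    return offsets


def flood_fill_largest(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Largest connected component by BFS, scanning seeds in lexicographic order.

    Ties in size resolve to the component discovered first, i.e. the one with
    the lexicographically smallest seed voxel.
    """
    offsets = _neighbor_offsets(connectivity)
    shape = mask.shape
    visited = np.zeros(shape, dtype=bool)
    best: list | None = None
    for seed in np.argwhere(mask):
        seed = tuple(int(v) for v in seed)
        if visited[seed]:
            continue
        component = []
        queue = deque([seed])
        visited[seed] = True
        while queue:
            x, y, z = queue.popleft()
            component.append((x, y, z))
            for dx, dy, dz in offsets:
                nx, ny, nz = x + dx, y + dy, z + dz
                if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                    if mask[nx, ny, nz] and not visited[nx, ny, nz]:
                        visited[nx, ny, nz] = True
                        queue.append((nx, ny, nz))
        if best is None or len(component) > len(best):
            best = component
    out = np.zeros(shape, dtype=bool)
    assert best is not None
    for voxel in best:
        out[voxel] = True
    return out


def pca_axis_oracle(points_mm: np.ndarray) -> np.ndarray:
    """Leading eigenvector of the covariance of an explicit point list."""
    centered = points_mm - points_mm.mean(axis=0)
    cov = centered.T @ centered / centered.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    axis = axis / np.linalg.norm(axis)
    if axis[2] < 0 or (axis[2] == 0 and axis[np.nonzero(axis)[0][0]] < 0):
        axis = -axis
    return axis


def _box_iou(a_lo, a_hi, b_lo, b_hi) -> float:
    inter = 1.0
    va = vb = 1.0
    for k in range(3):
        inter *= max(0.0, min(a_hi[k], b_hi[k]) - max(a_lo[k], b_lo[k]))
        va *= a_hi[k] - a_lo[k]
        vb *= b_hi[k] - b_lo[k]
    return inter / (va + vb - inter)


def greedy_match_tp(prefix, gts_by_image) -> int:
    """TP count after greedy confidence-ordered matching of a detection prefix.

    ``prefix`` is a list of (image_id, lo, hi) already sorted by descending
    confidence; each detection claims the unmatched ground truth of highest
    IoU >= 0.0 threshold handled by caller via filtering.
    """
    taken = {img: [False] * len(g) for img, g in gts_by_image.items()}
    tp = 0
    for image_id, lo, hi, iou_threshold in prefix:
        gts = gts_by_image.get(image_id, [])
        best_j, best_iou = -1, 0.0
        for j, (glo, ghi) in enumerate(gts):
            if taken[image_id][j]:
                continue
            iou = _box_iou(lo, hi, glo, ghi)
            if iou > best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[image_id][best_j] = True
            tp += 1
    return tp


def average_precision_oracle(dets, gts_by_image, iou_threshold: float) -> float:
    """AP by recomputing greedy matching from scratch for every prefix.

    ``dets``: list of (image_id, lo, hi, confidence). The PR curve is built
    from the per-prefix TP counts, given the monotone precision envelope, and
    read out at the 101 recall points 0.00 .. 1.00 with an explicit loop.
    """
    n_gt = sum(len(g) for g in gts_by_image.values())
    order = sorted(range(len(dets)), key=lambda i: (-dets[i][3], dets[i][0], i))
    recalls, precisions = [], []
    for k in range(1, len(order) + 1):
        prefix = [
            (dets[i][0], dets[i][1], dets[i][2], iou_threshold) for i in order[:k]
        ]
        tp = greedy_match_tp(prefix, gts_by_image)
        recalls.append(tp / n_gt)
        precisions.append(tp / k)
    # monotone envelope from the right
    for i in range(len(precisions) - 2, -1, -1):
        precisions[i] = max(precisions[i], precisions[i + 1])
    total = 0.0
    for r in np.linspace(0.0, 1.0, 101):  # the standard 101-point recall grid
        p = 0.0
        for rec, prec in zip(recalls, precisions):
            if rec >= r:
                p = prec
                break
        total += p
    return total / 101.0
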