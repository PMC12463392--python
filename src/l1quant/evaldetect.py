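"""Detection-quality evaluation: IoU matching and average precision.

AP here is the instance-segmentation convention AP = TP / (TP + FP + FN) at a
fixed IoU threshold (default 0.5).  Candidate (ground-truth, prediction)
pairs are every pair of instances with nonzero pixel overlap; pairs at or
above the IoU threshold are matched greedily by descending IoU with each
object used at most once (the StarDist-convention matcher).  At threshold
>= 0.5 and disjoint instances this greedy matching coincides with the
maximum-cardinality matching, which the test suite asserts against an
independent graph-matching oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MatchResult", "match_and_score"]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    ap: float
    iou_threshold: float
    pairs: list = field(default_factory=list)  # (gt_id, pred_id, iou)


def _overlap_table(gt: np.ndarray, pred: np.ndarray):
    """Pixel-overlap counts for every co-occurring (gt, pred) label pair."""
    both = (gt > 0) & (pred > 0)
    if not both.any():
        return {}, _sizes(gt), _sizes(pred)
    pairs = np.stack([gt[both], pred[both]])
    uniq, counts = np.unique(pairs, axis=1, return_counts=True)
    table = {
        (int(g), int(p)): int(c)
        for g, p, c in zip(uniq[0], uniq[1], counts)
    }
    return table, _sizes(gt), _sizes(pred)


def _sizes(labels: np.ndarray) -> dict:
    ids, counts = np.unique(labels, return_counts=True)
    return {int(i): int(c) for i, c in zip(ids, counts) if i != 0}


def match_and_score(
    gt_labels: np.ndarray, pred_labels: np.ndarray, iou_threshold: float = 0.5
) -> MatchResult:
    """Match predicted instances to ground truth and score AP.

    IoU ties are broken by (gt_id, pred_id) lexicographic order so the
    matching is fully deterministic.  Two empty maps score AP = 1.0 by
    convention; predictions against an empty ground truth score 0.
    """
    gt = np.asarray(gt_labels)
    pred = np.asarray(pred_labels)
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch: {gt.shape} vs {pred.shape}")
    if not 0 < iou_threshold <= 1:
        raise ValueError("iou_threshold must lie in (0, 1]")

    overlaps, gt_sizes, pred_sizes = _overlap_table(gt, pred)
    candidates = []
    for (g, p), inter in overlaps.items():
        union = gt_sizes[g] + pred_sizes[p] - inter
        iou = inter / union
        if iou >= iou_threshold:
            candidates.append((-iou, g, p))
    candidates.sort()

    used_gt, used_pred, pairs = set(), set(), []
    for neg_iou, g, p in candidates:
        if g in used_gt or p in used_pred:
            continue
        used_gt.add(g)
        used_pred.add(p)
        pairs.append((g, p, -neg_iou))

    tp = len(pairs)
    fp = len(pred_sizes) - tp
    fn = len(gt_sizes) - tp
    denom = tp + fp + fn
    ap = 1.0 if denom == 0 else tp / denom
    return MatchResult(tp=tp, fp=fp, fn=fn, ap=ap, iou_threshold=iou_threshold, pairs=pairs)
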