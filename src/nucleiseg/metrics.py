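"""Segmentation evaluation against ground-truth label masks.

Pixel-level overlap is summarized by the Dice similarity coefficient
``DSC = 2|A n B| / (|A| + |B|)`` on the whole-image foreground.  Object
detection is summarized by sensitivity ``SN = TP/(TP+FN)`` and positive
predictive value ``PPV = TP/(TP+FP)`` after greedy one-to-one matching of
predicted to ground-truth nuclei by descending IoU (a match counts as TP
when IoU >= 0.5, the field's convention; configurable).

Clump splitting is scored per ground-truth clump (a connected group of >= 2
touching nuclei): *undersplit* = the clump is covered by fewer predicted
objects than it holds nuclei; *oversplit* = a single nucleus is covered by
two or more predicted objects; *encroachment* = the object count is right
but the division runs along wrong boundaries (some best match below the IoU
threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import dilation as _binary_dilation

__all__ = [
    "MatchTable",
    "SegMetrics",
    "SplitMetrics",
    "dice_coefficient",
    "match_objects",
    "detection_metrics",
    "clump_regions_from_gt",
    "split_error_metrics",
]


@dataclass(frozen=True)
class MatchTable:
    """One-to-one object matching: (gt, pred, overlap, IoU) per accepted
    pair plus the leftovers on either side."""

    pairs: tuple[tuple[int, int, int, float], ...]
    unmatched_gt: tuple[int, ...]
    unmatched_pred: tuple[int, ...]

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred)


@dataclass(frozen=True)
class SegMetrics:
    """dsc/sn/ppv in [0, 1]; undefined ratios (empty denominator) are NaN."""

    dsc: float
    sn: float
    ppv: float
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class SplitMetrics:
    undersplit_rate: float
    oversplit_rate: float
    encroachment_rate: float
    n_clump_regions: int


def dice_coefficient(seg: np.ndarray, gt: np.ndarray) -> float:
    """Dice overlap of two binary masks; 1.0 when both are empty."""
    seg = np.asarray(seg, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if seg.shape != gt.shape:
        raise ValueError(f"shape mismatch: {seg.shape} vs {gt.shape}")
    denom = int(seg.sum()) + int(gt.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(seg & gt)) / denom


def _pairwise_overlaps(pred: np.ndarray, gt: np.ndarray):
    """Sparse contingency of overlapping (gt, pred) label pairs, with areas."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    gt_areas = {int(v): int(n) for v, n in zip(*np.unique(gt[gt > 0], return_counts=True))}
    pred_areas = {int(v): int(n) for v, n in zip(*np.unique(pred[pred > 0], return_counts=True))}
    both = (gt > 0) & (pred > 0)
    pairs, counts = np.unique(
        np.stack([gt[both], pred[both]]), axis=1, return_counts=True
    )
    overlaps = {
        (int(g), int(p)): int(n) for (g, p), n in zip(pairs.T, counts)
    }
    return gt_areas, pred_areas, overlaps


def match_objects(pred: np.ndarray, gt: np.ndarray, min_iou: float = 0.5) -> MatchTable:
    """Greedy one-to-one matching of predicted to ground-truth objects.

    Overlapping pairs are sorted by descending IoU (ties broken by label
    ids for determinism) and accepted greedily, each label used at most
    once; a pair is a TP iff its IoU >= ``min_iou``.
    """
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if not 0 < min_iou < 1:
        raise ValueError("min_iou must lie in (0, 1)")
    gt_areas, pred_areas, overlaps = _pairwise_overlaps(pred, gt)
    candidates = []
    for (g, p), inter in overlaps.items():
        union = gt_areas[g] + pred_areas[p] - inter
        iou = inter / union
        if iou >= min_iou:
            candidates.append((-iou, g, p, inter))
    candidates.sort()
    used_gt: set[int] = set()
    used_pred: set[int] = set()
    accepted = []
    for neg_iou, g, p, inter in candidates:
        if g in used_gt or p in used_pred:
            continue
        used_gt.add(g)
        used_pred.add(p)
        accepted.append((g, p, inter, -neg_iou))
    return MatchTable(
        pairs=tuple(accepted),
        unmatched_gt=tuple(sorted(set(gt_areas) - used_gt)),
        unmatched_pred=tuple(sorted(set(pred_areas) - used_pred)),
    )


def detection_metrics(table: MatchTable, pred: np.ndarray, gt: np.ndarray) -> SegMetrics:
    """SN/PPV from the match table, DSC on whole-image foreground masks.

    ``sn = TP/(TP+FN)`` and ``ppv = TP/(TP+FP)``; an empty denominator
    yields NaN (metric undefined, not zero).
    """
    tp, fp, fn = table.tp, table.fp, table.fn
    sn = tp / (tp + fn) if tp + fn > 0 else float("nan")
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    return SegMetrics(
        dsc=dice_coefficient(np.asarray(pred) > 0, np.asarray(gt) > 0),
        sn=sn,
        ppv=ppv,
        tp=tp,
        fp=fp,
        fn=fn,
    )


def clump_regions_from_gt(gt: np.ndarray) -> list[tuple[int, ...]]:
    """Connected groups of >= 2 touching ground-truth nuclei.

    Two nuclei touch when their masks are 8-adjacent (or share a boundary
    after the labels were carved out of one clump).  Groups are found by
    union-find over adjacent label pairs.
    """
    gt = np.asarray(gt)
    labels = [int(v) for v in np.unique(gt[gt > 0])]
    parent = {v: v for v in labels}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for lab in labels:
        ring = _binary_dilation(gt == lab, np.ones((3, 3), bool)) & (gt > 0) & (gt != lab)
        for neighbor in np.unique(gt[ring]):
            union(lab, int(neighbor))

    groups: dict[int, list[int]] = {}
    for lab in labels:
        groups.setdefault(find(lab), []).append(lab)
    return [tuple(sorted(g)) for g in sorted(groups.values()) if len(g) >= 2]


def split_error_metrics(
    pred: np.ndarray,
    gt: np.ndarray,
    clump_regions: list[tuple[int, ...]] | None = None,
    min_iou: float = 0.5,
    min_frac: float = 0.2,
) -> SplitMetrics:
    """Undersplit / oversplit / encroachment rates over ground-truth clumps.

    For each clump (group of touching gt nuclei): the predicted objects
    covering it are those covering >= ``min_frac`` of some member nucleus's
    area.  Each clump falls into at most one category, in priority order:
    *undersplit* — fewer covering objects than member nuclei;
    *encroachment* — counts agree but some member's best-IoU object is
    below ``min_iou`` (the division runs along wrong boundaries, which
    usually also makes objects straddle their neighbors);
    *oversplit* — otherwise, some single member nucleus is covered by >= 2
    objects (each covering >= ``min_frac`` of it).
    Rates are clump counts divided by the number of clumps; with no clumps
    all rates are NaN.
    """
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if clump_regions is None:
        clump_regions = clump_regions_from_gt(gt)
    n = len(clump_regions)
    if n == 0:
        return SplitMetrics(float("nan"), float("nan"), float("nan"), 0)

    gt_areas, pred_areas, overlaps = _pairwise_overlaps(pred, gt)
    by_gt: dict[int, list[tuple[int, int]]] = {}
    for (g, p), inter in overlaps.items():
        by_gt.setdefault(g, []).append((p, inter))

    under = over = encroach = 0
    for clump in clump_regions:
        covering: set[int] = set()
        is_over = False
        worst_best_iou = 1.0
        for g in clump:
            entries = by_gt.get(g, [])
            cover_g = [p for p, inter in entries if inter >= min_frac * gt_areas[g]]
            covering.update(cover_g)
            if len(cover_g) >= 2:
                is_over = True
            best_iou = 0.0
            for p, inter in entries:
                union_area = gt_areas[g] + pred_areas[p] - inter
                best_iou = max(best_iou, inter / union_area)
            worst_best_iou = min(worst_best_iou, best_iou)
        if len(covering) < len(clump):
            under += 1
        elif len(covering) == len(clump) and worst_best_iou < min_iou:
            encroach += 1
        elif is_over:
            over += 1
    return SplitMetrics(
        undersplit_rate=under / n,
        oversplit_rate=over / n,
        encroachment_rate=encroach / n,
        n_clump_regions=n,
    )
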