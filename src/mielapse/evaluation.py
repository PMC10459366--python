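"""Detection evaluation: IoU matching, precision/recall/F1, AP.

The protocol mirrors common practice for small-object benchmarks:

* a detection is a true positive if its box overlaps an unmatched
  ground-truth box with IoU strictly greater than a threshold (0.25 by
  default — small boxes carry high annotation uncertainty, so the usual
  0.5 is deliberately relaxed);
* matching is greedy in descending confidence order and one-to-one;
* precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2TP/(2TP+FP+FN),
  each defined as 0 when its denominator is 0;
* per-site metrics aggregate frame-level counts; the macro average is
  the unweighted mean of per-site metrics while the micro average is
  computed from the summed TP/FP/FN;
* AP is the area under the precision-recall curve with monotone
  (all-point) precision interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequence_io import Annotation, BoundingBox, Detection

IOU_THRESHOLD = 0.25


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two half-open pixel boxes."""
    ix = max(0.0, min(a.xmax, b.xmax) - max(a.xmin, b.xmin))
    iy = max(0.0, min(a.ymax, b.ymax) - max(a.ymin, b.ymin))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


@dataclass
class MatchResult:
    """Outcome of matching one frame's detections against its annotations."""

    tp: int
    fp: int
    fn: int
    matched_pairs: list[tuple[int, int, float]]


@dataclass
class SiteMetrics:
    """Per-site counts and derived metrics.

    Counts may be ``None`` for externally published metric rows where
    only recall/precision/F1 are available; such sites contribute to
    macro but not micro aggregation.
    """

    site_id: str
    recall: float
    precision: float
    f1: float
    tp: int | None = None
    fp: int | None = None
    fn: int | None = None

    @classmethod
    def from_counts(cls, site_id: str, tp: int, fp: int, fn: int) -> "SiteMetrics":
        p, r, f = prf1(tp, fp, fn)
        return cls(site_id=site_id, recall=r, precision=p, f1=f, tp=tp, fp=fp, fn=fn)


@dataclass
class AggregateMetrics:
    """Macro (mean of sites) and micro (pooled counts) averages.

    Micro fields are ``None`` when any site lacks raw counts.
    """

    macro_recall: float
    macro_precision: float
    macro_f1: float
    micro_recall: float | None
    micro_precision: float | None
    micro_f1: float | None


def prf1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """(precision, recall, f1) with the all-zero convention.

    Each metric is 0 when its denominator is 0, which keeps macro
    averaging total over insect-free sites and failed detectors.
    """
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (fp + tp) if (fp + tp) > 0 else 0.0
    recall = tp / (fn + tp) if (fn + tp) > 0 else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    return precision, recall, f1


def match_detections(
    dets: Sequence[Detection],
    anns: Sequence[Annotation],
    iou_threshold: float = IOU_THRESHOLD,
) -> MatchResult:
    """Greedy one-to-one matching of one frame's detections to annotations.

    Detections are visited in descending confidence (ties broken by
    ymin, then xmin); each claims the still-unmatched annotation with
    the highest IoU, provided that IoU is strictly greater than the
    threshold.  Unclaimed detections are false positives; unclaimed
    annotations are false negatives.
    """
    frame_ids = {d.frame_id for d in dets} | {a.frame_id for a in anns}
    if len(frame_ids) > 1:
        raise ValueError(f"mixed frame_ids in one match call: {sorted(frame_ids)}")
    order = sorted(
        range(len(dets)),
        key=lambda i: (-dets[i].confidence, dets[i].box.ymin, dets[i].box.xmin),
    )
    unmatched = set(range(len(anns)))
    pairs: list[tuple[int, int, float]] = []
    for di in order:
        best_j, best_iou = -1, iou_threshold
        for j in sorted(unmatched):
            v = iou(dets[di].box, anns[j].box)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0:
            unmatched.discard(best_j)
            pairs.append((di, best_j, best_iou))
    tp = len(pairs)
    return MatchResult(tp=tp, fp=len(dets) - tp, fn=len(anns) - tp,
                       matched_pairs=pairs)


def evaluate_site(
    detections_by_frame: Mapping[str, Sequence[Detection]],
    annotations_by_frame: Mapping[str, Sequence[Annotation]],
    iou_threshold: float = IOU_THRESHOLD,
    site_id: str = "",
) -> SiteMetrics:
    """Match frame by frame and pool TP/FP/FN over one site."""
    tp = fp = fn = 0
    for frame_id in sorted(set(detections_by_frame) | set(annotations_by_frame)):
        res = match_detections(
            list(detections_by_frame.get(frame_id, [])),
            list(annotations_by_frame.get(frame_id, [])),
            iou_threshold,
        )
        tp += res.tp
        fp += res.fp
        fn += res.fn
    return SiteMetrics.from_counts(site_id, tp, fp, fn)


def aggregate(sites: Sequence[SiteMetrics]) -> AggregateMetrics:
    """Macro (unweighted mean) and micro (pooled counts) averages."""
    if not sites:
        raise ValueError("need at least one site")
    macro_recall = float(np.mean([s.recall for s in sites]))
    macro_precision = float(np.mean([s.precision for s in sites]))
    macro_f1 = float(np.mean([s.f1 for s in sites]))
    if all(s.tp is not None and s.fp is not None and s.fn is not None for s in sites):
        tp = sum(s.tp for s in sites)
        fp = sum(s.fp for s in sites)
        fn = sum(s.fn for s in sites)
        micro_precision, micro_recall, micro_f1 = prf1(tp, fp, fn)
    else:
        micro_precision = micro_recall = micro_f1 = None
    return AggregateMetrics(
        macro_recall=macro_recall,
        macro_precision=macro_precision,
        macro_f1=macro_f1,
        micro_recall=micro_recall,
        micro_precision=micro_precision,
        micro_f1=micro_f1,
    )


def average_precision(
    ranked_results: Iterable[tuple[float, bool]],
    n_annotations: int,
) -> float:
    """Area under the precision-recall curve, all-point interpolation.

    ``ranked_results`` holds (confidence, is_true_positive) pairs; they
    are sorted by descending confidence (stable for ties).  Precision is
    made monotonically non-increasing from the right before integrating
    over the recall steps, the usual all-point interpolation rule.  The
    IoU threshold that defined true positives is the caller's choice
    (0.5 for AP@.5).
    """
    if n_annotations < 1:
        raise ValueError("n_annotations must be >= 1")
    results = sorted(ranked_results, key=lambda r: -r[0])
    if not results:
        return 0.0
    is_tp = np.array([bool(r[1]) for r in results])
    tp_cum = np.cumsum(is_tp)
    ranks = np.arange(1, len(results) + 1)
    precision = tp_cum / ranks
    recall = tp_cum / n_annotations
    # monotone envelope of precision, then sum rectangle areas at recall steps
    mpre = np.maximum.accumulate(precision[::-1])[::-1]
    prev_recall = 0.0
    ap = 0.0
    for p, r in zip(mpre, recall):
        if r > prev_recall:
            ap += (r - prev_recall) * p
            prev_recall = r
    return float(ap)
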