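"""Pairwise (two-reader) agreement: overlap scores, agreement matrix, NMS.

Two readers' calls on one image are compared through an *agreement
matrix*: an M x N table of overlap scores (pixel IOU, pixel DSC, or
bounding-box IOU) between every call of reader A and every call of
reader B.  Scores below the IOU/DSC threshold are rejected, and a
one-to-one matching is obtained by non-maximum suppression: a pair is
kept only when its score is maximal along both its row and its column of
the thresholded matrix.  This resolves *fragmenting* — one reader
drawing two calls where another draws one — by matching only the best
fragment; the other fragment remains a singleton call.

Matched pairs are the object-level true positives; unmatched calls on
either side are the false negatives / false positives, from which the
classical Jaccard (TP / (TP+FP+FN)) and Sørensen (2TP / (2TP+FP+FN))
indices follow.

Conventions fixed here (the source methods leave them open):

* Threshold comparison is **inclusive**: a score >= threshold survives.
* Exact score ties for a row or column maximum are broken toward the
  smaller (row, then column) index, so the matching is deterministic.
* A metric with no calls on either side is *undefined* (``None``), never
  silently 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .annotations import BBox, Call, Pixel

__all__ = [
    "AgreementMatrix",
    "MatchedPairs",
    "ConfusionCounts",
    "MetricKind",
    "mask_iou",
    "mask_dsc",
    "bbox_iou",
    "call_score",
    "agreement_matrix",
    "suppress_nonmaximum",
    "pairwise_confusion",
    "pairwise_indices",
]

MetricKind = Literal["mask_iou", "mask_dsc", "bbox_iou"]


def mask_iou(a: frozenset[Pixel] | set, b: frozenset[Pixel] | set) -> float:
    """Pixel intersection over union, |a∩b| / |a∪b|, as a ratio of counts."""
    if not a or not b:
        raise ValueError("mask_iou requires non-empty pixel sets")
    inter = len(a & b)
    return inter / (len(a) + len(b) - inter)


def mask_dsc(a: frozenset[Pixel] | set, b: frozenset[Pixel] | set) -> float:
    """Dice–Sørensen coefficient, 2|a∩b| / (|a|+|b|); equals 2·IOU/(1+IOU)."""
    if not a or not b:
        raise ValueError("mask_dsc requires non-empty pixel sets")
    return 2 * len(a & b) / (len(a) + len(b))


def _bbox_area(b: BBox) -> int:
    xmin, ymin, xmax, ymax = b
    return (xmax - xmin + 1) * (ymax - ymin + 1)


def bbox_iou(a: BBox, b: BBox) -> float:
    """IOU of two inclusive pixel bounding boxes (area = (xmax-xmin+1)·(ymax-ymin+1))."""
    for box in (a, b):
        if len(box) != 4 or box[0] > box[2] or box[1] > box[3]:
            raise ValueError(f"malformed bbox {box}")
    ixmin, iymin = max(a[0], b[0]), max(a[1], b[1])
    ixmax, iymax = min(a[2], b[2]), min(a[3], b[3])
    if ixmin > ixmax or iymin > iymax:
        return 0.0
    inter = (ixmax - ixmin + 1) * (iymax - iymin + 1)
    return inter / (_bbox_area(a) + _bbox_area(b) - inter)


def call_score(a: Call, b: Call, metric_kind: MetricKind) -> float:
    """Overlap score of two calls under the given metric."""
    if metric_kind in ("mask_iou", "mask_dsc"):
        if a.mask is None or b.mask is None:
            raise ValueError(f"{metric_kind} requires masks on both calls")
        fn = mask_iou if metric_kind == "mask_iou" else mask_dsc
        return fn(a.mask, b.mask)
    if metric_kind == "bbox_iou":
        ba = a.bbox if a.bbox is not None else a.with_tight_bbox().bbox
        bb = b.bbox if b.bbox is not None else b.with_tight_bbox().bbox
        return bbox_iou(ba, bb)
    raise ValueError(f"unknown metric kind {metric_kind!r}")


@dataclass
class AgreementMatrix:
    """M x N overlap scores between all calls of two readers on one image."""

    reader_a: str
    reader_b: str
    image_id: str
    scores: np.ndarray
    metric_kind: MetricKind

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("agreement scores must lie in [0,1]")


@dataclass(frozen=True)
class MatchedPairs:
    """One-to-one matching surviving threshold + NMS; pairs of call indices."""

    pairs: frozenset[tuple[int, int]]
    threshold: float


@dataclass(frozen=True)
class ConfusionCounts:
    """Object-level confusion counts with reader A as reference.

    True negatives are deliberately absent: they are undefined for object
    detection.  Swapping which reader is the reference swaps fp and fn.
    """

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def _tight_bbox_of(call: Call) -> BBox:
    if call.bbox is not None:
        return call.bbox
    return call.with_tight_bbox().bbox  # type: ignore[return-value]


def agreement_matrix(
    calls_a: Sequence[Call],
    calls_b: Sequence[Call],
    metric_kind: MetricKind = "mask_iou",
) -> AgreementMatrix:
    """Score every call of reader A against every call of reader B.

    Zero rows/columns (a reader with no calls) are allowed and flow
    through to TP=0 downstream.  Bounding boxes are used as a cheap
    disjointness prefilter for the mask metrics: calls whose boxes do
    not overlap have score 0 without touching pixels.
    """
    image_ids = {c.image_id for c in calls_a} | {c.image_id for c in calls_b}
    if len(image_ids) > 1:
        raise ValueError(f"calls span multiple images: {sorted(image_ids)}")
    image_id = next(iter(image_ids)) if image_ids else ""
    reader_a = calls_a[0].reader_id if calls_a else ""
    reader_b = calls_b[0].reader_id if calls_b else ""
    scores = np.zeros((len(calls_a), len(calls_b)))
    boxes_a = [_tight_bbox_of(c) for c in calls_a]
    boxes_b = [_tight_bbox_of(c) for c in calls_b]
    for i, ca in enumerate(calls_a):
        ax0, ay0, ax1, ay1 = boxes_a[i]
        for j, cb in enumerate(calls_b):
            bx0, by0, bx1, by1 = boxes_b[j]
            if bx0 > ax1 or ax0 > bx1 or by0 > ay1 or ay0 > by1:
                continue  # disjoint boxes => score 0 for every metric kind
            scores[i, j] = call_score(ca, cb, metric_kind)
    return AgreementMatrix(
        reader_a=reader_a,
        reader_b=reader_b,
        image_id=image_id,
        scores=scores,
        metric_kind=metric_kind,
    )


def suppress_nonmaximum(m: AgreementMatrix | np.ndarray, threshold: float) -> MatchedPairs:
    """Threshold the agreement matrix and keep only row-and-column maxima.

    An entry ``(i, j)`` is retained iff ``scores[i, j] >= threshold``
    (inclusive) and it is the tie-broken maximum of row ``i`` and of
    column ``j`` among surviving entries; exact ties go to the smaller
    (row, then column) index.  Each call therefore appears in at most
    one retained pair.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0,1], got {threshold}")
    scores = m.scores if isinstance(m, AgreementMatrix) else np.asarray(m, dtype=float)
    s = np.where(scores >= threshold, scores, 0.0)
    pairs = set()
    nrow, ncol = s.shape
    for i in range(nrow):
        for j in range(ncol):
            v = s[i, j]
            if v < threshold:
                continue
            # tie-broken argmax of row i: highest score, then smallest column
            row = s[i]
            best_j = min(np.flatnonzero(row == row.max()))
            if row.max() != v or best_j != j:
                continue
            col = s[:, j]
            best_i = min(np.flatnonzero(col == col.max()))
            if col.max() != v or best_i != i:
                continue
            pairs.add((i, j))
    return MatchedPairs(pairs=frozenset(pairs), threshold=threshold)


def pairwise_confusion(pairs: MatchedPairs, n_calls_a: int, n_calls_b: int) -> ConfusionCounts:
    """Confusion counts with reader A as reference: tp=|pairs|, fn=M-tp, fp=N-tp."""
    tp = len(pairs.pairs)
    if tp > n_calls_a or tp > n_calls_b:
        raise ValueError(
            f"{tp} matched pairs exceed call counts ({n_calls_a}, {n_calls_b})"
        )
    return ConfusionCounts(tp=tp, fp=n_calls_b - tp, fn=n_calls_a - tp)


def pairwise_indices(c: ConfusionCounts) -> tuple[float | None, float | None]:
    """Jaccard = TP/(TP+FP+FN) and Sørensen = 2TP/(2TP+FP+FN).

    Both are ``None`` (undefined) when neither reader made a call
    (TP+FP+FN = 0); 0/0 has no natural value and silent defaults would
    bias image-level means.
    """
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return None, None
    return c.tp / denom, 2 * c.tp / (2 * c.tp + c.fp + c.fn)
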