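"""Multireader Jaccard and Sørensen indices and image-level summaries.

Let C_j be the number of calls reader j made on an image and O_k the
number of consensus objects called by exactly k readers (1 <= k <= N_R),
at a given IOU/DSC threshold.  Writing C = Σ_j C_j and O = Σ_k O_k, the
multireader generalizations are

    J = (C - O) / ((N_R - 1) · O)                    (multireader Jaccard)
    S = N_R · J / (N_R - 1 + J)                      (multireader Sørensen)
      = N_R (C - O) / ((N_R - 1)² O + C - O)

For two readers C = 2TP + FP + FN and O = TP + FP + FN, so J and S
reduce exactly to the confusion-matrix forms TP/(TP+FP+FN) and
2TP/(2TP+FP+FN).  Perfect agreement (every object called by all N_R
readers) gives 1; no two calls ever matching (O = C) gives 0.  When no
reader calls anything (O = 0) the indices are undefined and excluded
from aggregation.

Both indices are computed per image and aggregated across images with a
95% t-interval of the mean; pooling raw counts across images before
dividing is available behind an explicit flag but is not the default
methodology.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .annotations import ReaderAnnotationSet
from .consensus import MatchMatrix, build_match_matrix
from .pairwise import MetricKind, pairwise_confusion, pairwise_indices
from .consensus import pairwise_matches_for_image

__all__ = [
    "MultireaderCounts",
    "count_calls_and_objects",
    "multireader_jaccard",
    "multireader_sorensen",
    "multireader_indices_for_image",
    "mean_pairwise_index",
    "aggregate_over_images",
    "pooled_counts",
]


@dataclass(frozen=True)
class MultireaderCounts:
    """Per-image tallies feeding the multireader indices."""

    n_readers: int
    calls_per_reader: tuple[int, ...]
    objects_by_k: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.n_readers < 2:
            raise ValueError("multireader counts require >= 2 readers")
        object.__setattr__(self, "calls_per_reader", tuple(self.calls_per_reader))
        object.__setattr__(self, "objects_by_k", tuple(self.objects_by_k))
        if len(self.calls_per_reader) != self.n_readers:
            raise ValueError("calls_per_reader length must equal n_readers")
        if len(self.objects_by_k) != self.n_readers:
            raise ValueError("objects_by_k must have one entry per k = 1..N_R")
        if min(self.calls_per_reader, default=0) < 0 or min(self.objects_by_k, default=0) < 0:
            raise ValueError("counts must be non-negative")
        conserved = sum(k * o for k, o in enumerate(self.objects_by_k, start=1))
        if conserved != sum(self.calls_per_reader):
            raise ValueError(
                f"call conservation violated: sum k*O_k = {conserved} but "
                f"sum C_j = {sum(self.calls_per_reader)}"
            )

    @property
    def total_calls(self) -> int:
        return sum(self.calls_per_reader)

    @property
    def total_objects(self) -> int:
        return sum(self.objects_by_k)


def count_calls_and_objects(mm: MatchMatrix) -> MultireaderCounts:
    """Tally C_j and O_k from a match matrix."""
    n_r = len(mm.readers)
    calls = [0] * n_r
    objects = [0] * n_r
    for obj in mm.objects:
        objects[len(obj) - 1] += 1
        for reader in obj:
            calls[mm.readers.index(reader)] += 1
    return MultireaderCounts(
        n_readers=n_r, calls_per_reader=tuple(calls), objects_by_k=tuple(objects)
    )


def multireader_jaccard(c: MultireaderCounts, exact: bool = False):
    """(ΣC − ΣO) / ((N_R − 1)·ΣO); ``None`` when no objects exist.

    With ``exact=True`` the value is returned as a :class:`~fractions.Fraction`
    so the two-reader reduction to TP/(TP+FP+FN) can be checked as
    rational arithmetic, not floating point.
    """
    if c.total_objects == 0:
        return None
    value = Fraction(c.total_calls - c.total_objects, (c.n_readers - 1) * c.total_objects)
    return value if exact else float(value)


def multireader_sorensen(c: MultireaderCounts, exact: bool = False):
    """N_R·J / (N_R − 1 + J); ``None`` when J is undefined."""
    j = multireader_jaccard(c, exact=True)
    if j is None:
        return None
    value = c.n_readers * j / (c.n_readers - 1 + j)
    return value if exact else float(value)


def multireader_indices_for_image(
    annsets: Sequence[ReaderAnnotationSet],
    image_id: str,
    metric_kind: MetricKind = "mask_iou",
    threshold: float = 0.5,
) -> tuple[float | None, float | None]:
    """Convenience: build the match matrix and return (J, S) for one image."""
    mm = build_match_matrix(annsets, image_id, metric_kind, threshold)
    counts = count_calls_and_objects(mm)
    return multireader_jaccard(counts), multireader_sorensen(counts)


def mean_pairwise_index(
    annsets: Sequence[ReaderAnnotationSet],
    image_id: str,
    metric_kind: MetricKind = "mask_iou",
    threshold: float = 0.5,
    which: Literal["jaccard", "sorensen"] = "jaccard",
) -> float | None:
    """Mean of the defined pairwise index over all N_R(N_R−1)/2 reader pairs.

    This is the baseline the multireader indices are contrasted with:
    pairwise comparisons are not independent and their mean typically
    sits above the multireader value.  Undefined pairs (neither reader
    called anything) are excluded; ``None`` if every pair is undefined.
    """
    if len(annsets) < 2:
        raise ValueError("mean pairwise index requires >= 2 readers")
    if which not in ("jaccard", "sorensen"):
        raise ValueError(f"unknown index {which!r}")
    by_reader = {s.reader_id: s for s in annsets}
    values = []
    for (ra, rb), mp in pairwise_matches_for_image(
        annsets, image_id, metric_kind, threshold
    ).items():
        cc = pairwise_confusion(
            mp, by_reader[ra].n_calls(image_id), by_reader[rb].n_calls(image_id)
        )
        j, s = pairwise_indices(cc)
        value = j if which == "jaccard" else s
        if value is not None:
            values.append(value)
    return float(np.mean(values)) if values else None


def aggregate_over_images(
    values: Sequence[float | None], confidence: float = 0.95
) -> tuple[float, float, float, int]:
    """Mean of the defined per-image values with a two-sided t-interval.

    Returns ``(mean, ci_low, ci_high, n_undefined)``.  Undefined values
    are excluded and counted; all-undefined input is an error.
    """
    defined = np.asarray([v for v in values if v is not None], dtype=float)
    n_undefined = len(values) - defined.size
    if defined.size == 0:
        raise ValueError("no defined values to aggregate")
    mean = float(defined.mean())
    if defined.size == 1 or float(defined.std(ddof=1)) == 0.0:
        return mean, mean, mean, n_undefined
    sem = stats.sem(defined)
    low, high = stats.t.interval(confidence, defined.size - 1, loc=mean, scale=sem)
    return mean, float(low), float(high), n_undefined


def pooled_counts(counts: Sequence[MultireaderCounts]) -> MultireaderCounts:
    """Pool raw counts across images (non-default aggregation mode)."""
    if not counts:
        raise ValueError("nothing to pool")
    n_r = counts[0].n_readers
    if any(c.n_readers != n_r for c in counts):
        raise ValueError("cannot pool counts with differing reader numbers")
    calls = tuple(sum(c.calls_per_reader[j] for c in counts) for j in range(n_r))
    objs = tuple(sum(c.objects_by_k[k] for c in counts) for k in range(n_r))
    return MultireaderCounts(n_readers=n_r, calls_per_reader=calls, objects_by_k=objs)
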