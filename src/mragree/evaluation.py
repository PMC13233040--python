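"""Reader and algorithm evaluation protocols built on the multireader indices.

Four procedures:

* **Leave-one-reader-out** — per-image multireader Jaccard of the full
  panel vs. each panel of N_R − 1 readers, testing whether agreement
  rises when a reader is excluded (a reader performing out of
  distribution is the one whose exclusion significantly raises the
  group index).
* **Candidate-as-extra-reader** — an algorithm's annotations join the
  human panel as one more reader; the group index with and without the
  candidate is compared per threshold, with a noninferiority bound on
  the paired per-image differences.
* **Noninferiority bound** — lower limit of a one-sided 90% confidence
  interval for the mean paired difference (group-with-candidate minus
  group-without); a bound near or above zero means adding the candidate
  does not degrade agreement.  Seeded percentile bootstrap by default,
  t-based construction as an option.
* **Stringency curve** — the candidate evaluated with the pairwise
  Jaccard index against curated ground-truth sets requiring
  min_calls = 1..N_R readers per object, with a Kruskal–Wallis test
  across stringencies.

Hypothesis tests are delegated to scipy (Mann–Whitney U, Kruskal–
Wallis); the wrappers only fix the alternatives, the comparison counts,
and the Bonferroni correction the protocol prescribes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotations import ReaderAnnotationSet
from .consensus import (
    build_match_matrix,
    curate_ground_truth,
    pairwise_matches_for_image,
)
from .metrics import count_calls_and_objects, multireader_jaccard, multireader_sorensen
from .pairwise import (
    MetricKind,
    agreement_matrix,
    pairwise_confusion,
    pairwise_indices,
    suppress_nonmaximum,
)

__all__ = [
    "GroupComparison",
    "StringencyCurve",
    "mwu_bonferroni",
    "kruskal_wallis",
    "per_image_group_index",
    "leave_one_out",
    "compare_with_candidate",
    "noninferiority_lower_bound",
    "stringency_curve",
]


@dataclass
class GroupComparison:
    """One tested contrast between two reader groups' per-image metrics."""

    label_a: str
    label_b: str
    per_image_a: list[float]
    per_image_b: list[float]
    adjusted_p: float | None
    n_comparisons_for_correction: int
    raw_p: float | None = None
    noninferiority_lower: float | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        if len(self.per_image_a) != len(self.per_image_b):
            raise ValueError("per-image samples must be aligned (equal length)")


@dataclass
class StringencyCurve:
    """Candidate-vs-curated-set Jaccard at each agreement stringency."""

    values: dict[int, list[float]]
    kruskal_p: float
    threshold: float


def mwu_bonferroni(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    m_comparisons: int = 1,
    alternative: Literal["two-sided", "less", "greater"] = "two-sided",
) -> float:
    """Mann–Whitney U p-value for a vs b, Bonferroni-multiplied and capped at 1."""
    if len(sample_a) == 0 or len(sample_b) == 0:
        raise ValueError("Mann–Whitney test requires non-empty samples")
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    p = stats.mannwhitneyu(sample_a, sample_b, alternative=alternative).pvalue
    return min(1.0, float(p) * m_comparisons)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> float:
    """Kruskal–Wallis p-value across >= 2 non-empty groups."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("Kruskal–Wallis requires >= 2 non-empty groups")
    return float(stats.kruskal(*groups).pvalue)


def _sorted_common_images(annsets: Sequence[ReaderAnnotationSet]) -> list[str]:
    common = set(annsets[0].images)
    for s in annsets[1:]:
        common &= set(s.images)
    return sorted(common)


def per_image_group_index(
    annsets: Sequence[ReaderAnnotationSet],
    image_ids: Sequence[str] | None = None,
    metric_kind: MetricKind = "mask_iou",
    threshold: float = 0.5,
    which: Literal["jaccard", "sorensen"] = "jaccard",
    pair_cache: Mapping[str, Mapping] | None = None,
) -> dict[str, float | None]:
    """Per-image multireader index for one reader group.

    ``pair_cache`` maps image_id to precomputed pairwise matches of a
    superset group (see :func:`pairwise_matches_for_image`); subset
    evaluations then reuse them instead of rescoring masks.
    """
    if image_ids is None:
        image_ids = _sorted_common_images(annsets)
    out: dict[str, float | None] = {}
    for image_id in image_ids:
        pairs = pair_cache.get(image_id) if pair_cache is not None else None
        mm = build_match_matrix(
            annsets, image_id, metric_kind, threshold, pair_matches=pairs
        )
        counts = count_calls_and_objects(mm)
        fn = multireader_jaccard if which == "jaccard" else multireader_sorensen
        out[image_id] = fn(counts)
    return out


def _paired_defined(
    a: Mapping[str, float | None], b: Mapping[str, float | None]
) -> tuple[list[float], list[float]]:
    xs, ys = [], []
    for image_id in sorted(a):
        if a[image_id] is not None and b.get(image_id) is not None:
            xs.append(a[image_id])
            ys.append(b[image_id])
    return xs, ys


def leave_one_out(
    annsets: Sequence[ReaderAnnotationSet],
    metric_kind: MetricKind = "mask_iou",
    threshold: float = 0.5,
    m_comparisons: int | None = None,
) -> list[GroupComparison]:
    """Compare the full panel with every panel of N_R − 1 readers.

    One comparison per excluded reader, one-sided toward the smaller
    group having the higher per-image multireader Jaccard, Bonferroni-
    corrected over the number of comparisons (default: N_R).
    """
    n_r = len(annsets)
    if n_r < 3:
        raise ValueError("leave-one-out requires >= 3 readers")
    if m_comparisons is None:
        m_comparisons = n_r
    images = _sorted_common_images(annsets)
    cache = {
        image_id: pairwise_matches_for_image(annsets, image_id, metric_kind, threshold)
        for image_id in images
    }
    full = per_image_group_index(
        annsets, images, metric_kind, threshold, pair_cache=cache
    )
    full_label = "+".join(s.reader_id for s in annsets)
    comparisons = []
    for excluded in range(n_r):
        subset = [s for i, s in enumerate(annsets) if i != excluded]
        sub = per_image_group_index(
            subset, images, metric_kind, threshold, pair_cache=cache
        )
        full_vals, sub_vals = _paired_defined(full, sub)
        adjusted = (
            mwu_bonferroni(sub_vals, full_vals, m_comparisons, alternative="greater")
            if full_vals
            else None
        )
        raw = (
            mwu_bonferroni(sub_vals, full_vals, 1, alternative="greater")
            if full_vals
            else None
        )
        comparisons.append(
            GroupComparison(
                label_a=full_label,
                label_b=f"without {annsets[excluded].reader_id}",
                per_image_a=full_vals,
                per_image_b=sub_vals,
                adjusted_p=adjusted,
                n_comparisons_for_correction=m_comparisons,
                raw_p=raw,
                threshold=threshold,
            )
        )
    return comparisons


def compare_with_candidate(
    annsets: Sequence[ReaderAnnotationSet],
    candidate: ReaderAnnotationSet,
    metric_kind: MetricKind = "mask_iou",
    thresholds: Sequence[float] = (0.25, 0.5, 0.75),
    which: Literal["jaccard", "sorensen"] = "jaccard",
    noninferiority_level: float = 0.90,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> list[GroupComparison]:
    """Treat the candidate as one more reader and compare group agreement.

    Per threshold: per-image multireader index of the human-only group
    (sample a) vs. humans + candidate (sample b), a two-sided Mann–
    Whitney test Bonferroni-corrected over the thresholds tested, and
    the noninferiority lower bound of the paired differences
    (with-candidate minus without).
    """
    images = _sorted_common_images(annsets)
    if set(candidate.images) < set(images):
        missing = sorted(set(images) - set(candidate.images))
        raise ValueError(f"candidate does not cover images: {missing}")
    joint = list(annsets) + [candidate]
    m = len(thresholds)
    comparisons = []
    for t_i, threshold in enumerate(thresholds):
        humans = per_image_group_index(annsets, images, metric_kind, threshold, which)
        with_cand = per_image_group_index(joint, images, metric_kind, threshold, which)
        a_vals, b_vals = _paired_defined(humans, with_cand)
        diffs = [b - a for a, b in zip(a_vals, b_vals)]
        bound = (
            noninferiority_lower_bound(
                diffs,
                level=noninferiority_level,
                n_boot=n_boot,
                seed=None if seed is None else seed + t_i,
            )
            if len(diffs) >= 2
            else None
        )
        comparisons.append(
            GroupComparison(
                label_a="+".join(s.reader_id for s in annsets),
                label_b=f"with {candidate.reader_id}",
                per_image_a=a_vals,
                per_image_b=b_vals,
                adjusted_p=mwu_bonferroni(a_vals, b_vals, m) if a_vals else None,
                n_comparisons_for_correction=m,
                raw_p=mwu_bonferroni(a_vals, b_vals, 1) if a_vals else None,
                noninferiority_lower=bound,
                threshold=threshold,
            )
        )
    return comparisons


def noninferiority_lower_bound(
    per_image_diffs: Sequence[float | None],
    level: float = 0.90,
    n_boot: int = 10_000,
    seed: int | None = None,
    method: Literal["bootstrap", "t"] = "bootstrap",
) -> float:
    """Lower bound of the one-sided ``level`` CI of the mean paired difference.

    Bootstrap (default): the ``1 - level`` quantile of ``n_boot``
    resampled means over images, deterministic for a fixed seed.
    ``method="t"``: mean − t_{level, n−1} · SEM.
    """
    diffs = np.asarray([d for d in per_image_diffs if d is not None], dtype=float)
    if diffs.size < 2:
        raise ValueError("need >= 2 defined paired differences")
    if not (0.5 < level < 1.0):
        raise ValueError("level must be in (0.5, 1)")
    if method == "t":
        sem = stats.sem(diffs)
        return float(diffs.mean() - stats.t.ppf(level, diffs.size - 1) * sem)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, diffs.size, size=(n_boot, diffs.size))
    boot_means = diffs[idx].mean(axis=1)
    return float(np.quantile(boot_means, 1.0 - level))


def _candidate_vs_reference(
    candidate: ReaderAnnotationSet,
    reference: ReaderAnnotationSet,
    image_id: str,
    metric_kind: MetricKind,
    threshold: float,
) -> float | None:
    m = agreement_matrix(
        reference.calls(image_id), candidate.calls(image_id), metric_kind
    )
    mp = suppress_nonmaximum(m, threshold)
    cc = pairwise_confusion(mp, reference.n_calls(image_id), candidate.n_calls(image_id))
    jaccard, _ = pairwise_indices(cc)
    return jaccard


def stringency_curve(
    annsets: Sequence[ReaderAnnotationSet],
    candidate: ReaderAnnotationSet,
    metric_kind: MetricKind = "mask_iou",
    threshold: float = 0.5,
) -> StringencyCurve:
    """Evaluate the candidate against curated sets of rising stringency.

    For each min_calls k = 1..N_R, the consensus objects called by at
    least k readers form a ground-truth set, and the candidate's
    per-image pairwise Jaccard against that set is collected (pairwise,
    not multireader, because the curated set is a single reference).
    A Kruskal–Wallis test across the k groups asks whether apparent
    candidate performance depends on the stringency choice.
    """
    if len(annsets) < 2:
        raise ValueError("stringency curve requires >= 2 panel readers")
    n_r = len(annsets)
    images = _sorted_common_images(list(annsets) + [candidate])
    values: dict[int, list[float]] = {k: [] for k in range(1, n_r + 1)}
    for image_id in images:
        mm = build_match_matrix(annsets, image_id, metric_kind, threshold)
        for k in range(1, n_r + 1):
            curated = curate_ground_truth(mm, annsets, min_calls=k)
            j = _candidate_vs_reference(candidate, curated, image_id, metric_kind, threshold)
            if j is not None:
                values[k].append(j)
    testable = [v for v in values.values() if v]
    p = kruskal_wallis(testable) if len(testable) >= 2 else float("nan")
    return StringencyCurve(values=values, kruskal_p=p, threshold=threshold)
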