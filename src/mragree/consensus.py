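"""Consensus across an arbitrary number of readers: the match matrix.

For N_R readers an agreement matrix is computed for each of the
N_R(N_R-1)/2 unique reader pairs, thresholded, and reduced to one-to-one
matched pairs by non-maximum suppression.  Calls are then linked across
pairs: consensus *objects* are the connected components of the graph
whose nodes are calls and whose edges are retained pairs.  The result is
the *match matrix* — N_A objects by N_R readers, each cell holding the
index of the reader's matched call (blank where a reader missed the
object).  Each object carries the count k of readers who called it,
1 <= k <= N_R.

Transitive linking can conflict with the one-call-per-reader-per-object
constraint (A0–B0 and B0–C0 matched, but C0 also matched to A1).  While
any component contains two calls from the same reader, the lowest-score
edge in that component is deleted and components are recomputed; exact
score ties are broken by edge insertion order.  Deletions are recorded
on the result (`MatchMatrix.dropped_edges`) and logged, since they mark
genuinely ambiguous annotation geometry.

The match matrix maps onto a *layered* image representation: a stack of
N_R label images in which layer k holds the consensus masks of objects
called by exactly k readers.  Filtering objects by a minimum k curates a
single ground-truth set at any agreement stringency.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .annotations import Call, ReaderAnnotationSet
from .pairwise import MatchedPairs, MetricKind, agreement_matrix, call_score, suppress_nonmaximum

__all__ = [
    "MatchMatrix",
    "LayeredConsensus",
    "pairwise_matches_for_image",
    "build_match_matrix",
    "layered_representation",
    "curate_ground_truth",
    "write_match_matrix_json",
    "read_match_matrix_json",
    "write_layered_tiff",
]

logger = logging.getLogger(__name__)


@dataclass
class MatchMatrix:
    """N_A consensus objects x N_R readers; entries are matched call indices."""

    image_id: str
    readers: tuple[str, ...]
    objects: list[dict[str, int]]
    metric_kind: MetricKind = "mask_iou"
    threshold: float = 0.5
    #: edges removed to restore the one-call-per-reader constraint,
    #: as ((reader, call_index), (reader, call_index), score)
    dropped_edges: list[tuple[tuple[str, int], tuple[str, int], float]] = field(
        default_factory=list
    )

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def k_of(self, obj: Mapping[str, int]) -> int:
        return len(obj)

    def objects_with_min_calls(self, min_calls: int) -> list[dict[str, int]]:
        return [o for o in self.objects if len(o) >= min_calls]

    def validate(self, n_calls_per_reader: Mapping[str, int] | None = None) -> None:
        seen: set[tuple[str, int]] = set()
        for obj in self.objects:
            if not obj:
                raise ValueError("empty consensus object")
            if len(obj) > len(self.readers):
                raise ValueError("object has more entries than readers")
            for reader, idx in obj.items():
                if reader not in self.readers:
                    raise ValueError(f"unknown reader {reader!r} in object")
                key = (reader, idx)
                if key in seen:
                    raise ValueError(f"call {key} appears in more than one object")
                seen.add(key)
        if n_calls_per_reader is not None:
            expected = {
                (r, i) for r, n in n_calls_per_reader.items() for i in range(n)
            }
            if seen != expected:
                raise ValueError("match matrix does not partition the calls")


def pairwise_matches_for_image(
    annsets: Sequence[ReaderAnnotationSet],
    image_id: str,
    metric_kind: MetricKind = "mask_iou",
    threshold: float = 0.5,
) -> dict[tuple[str, str], MatchedPairs]:
    """Matched pairs for every unique reader pair (N_R(N_R-1)/2 comparisons)."""
    out = {}
    for sa, sb in combinations(annsets, 2):
        m = agreement_matrix(sa.calls(image_id), sb.calls(image_id), metric_kind)
        out[(sa.reader_id, sb.reader_id)] = suppress_nonmaximum(m, threshold)
    return out


def _component_conflict(graph: nx.Graph, component: set) -> bool:
    readers = [node[0] for node in component]
    return len(readers) != len(set(readers))


def build_match_matrix(
    annsets: Sequence[ReaderAnnotationSet],
    image_id: str,
    metric_kind: MetricKind = "mask_iou",
    threshold: float = 0.5,
    pair_matches: Mapping[tuple[str, str], MatchedPairs] | None = None,
) -> MatchMatrix:
    """Link pairwise matches into consensus objects for one image.

    ``pair_matches`` may supply precomputed matched pairs keyed by
    ``(reader_a, reader_b)`` in the order readers appear in ``annsets``
    (as produced by :func:`pairwise_matches_for_image`); evaluation
    loops over reader subsets reuse one computation this way.
    Unmatched calls become singleton objects, so the matrix partitions
    every call of every reader.
    """
    if len(annsets) < 2:
        raise ValueError("consensus requires at least 2 readers")
    readers = tuple(s.reader_id for s in annsets)
    if len(set(readers)) != len(readers):
        raise ValueError("duplicate reader_id in annotation sets")
    if pair_matches is None:
        pair_matches = pairwise_matches_for_image(annsets, image_id, metric_kind, threshold)

    by_reader = {s.reader_id: s for s in annsets}
    score_cache: dict[tuple[tuple[str, int], tuple[str, int]], float] = {}

    def edge_score(u: tuple[str, int], v: tuple[str, int]) -> float:
        key = (u, v)
        if key not in score_cache:
            ca = by_reader[u[0]].calls(image_id)[u[1]]
            cb = by_reader[v[0]].calls(image_id)[v[1]]
            score_cache[key] = call_score(ca, cb, metric_kind)
        return score_cache[key]

    graph = nx.Graph()
    for reader in readers:
        for call in by_reader[reader].calls(image_id):
            graph.add_node((reader, call.call_index))
    edge_order = 0
    for sa, sb in combinations(annsets, 2):
        mp = pair_matches[(sa.reader_id, sb.reader_id)]
        for i, j in sorted(mp.pairs):
            u, v = (sa.reader_id, i), (sb.reader_id, j)
            graph.add_edge(u, v, score=edge_score(u, v), order=edge_order)
            edge_order += 1

    # resolve transitive conflicts: drop the weakest edge of any component
    # holding two calls from one reader, ties broken by insertion order
    dropped: list[tuple[tuple[str, int], tuple[str, int], float]] = []
    while True:
        conflicted = [c for c in nx.connected_components(graph) if _component_conflict(graph, c)]
        if not conflicted:
            break
        for component in conflicted:
            edges = list(graph.subgraph(component).edges(data=True))
            u, v, data = min(edges, key=lambda e: (e[2]["score"], e[2]["order"]))
            graph.remove_edge(u, v)
            dropped.append((u, v, data["score"]))
            logger.info(
                "image %s: dropped edge %s-%s (score %.3f) to restore "
                "one-call-per-reader consensus",
                image_id,
                u,
                v,
                data["score"],
            )

    reader_rank = {r: k for k, r in enumerate(readers)}
    objects = []
    for component in nx.connected_components(graph):
        obj = {reader: idx for reader, idx in component}
        objects.append(obj)
    # deterministic object order: by first (reader rank, call index) member
    objects.sort(key=lambda o: min((reader_rank[r], i) for r, i in o.items()))

    mm = MatchMatrix(
        image_id=image_id,
        readers=readers,
        objects=objects,
        metric_kind=metric_kind,
        threshold=threshold,
        dropped_edges=dropped,
    )
    mm.validate({r: by_reader[r].n_calls(image_id) for r in readers})
    return mm


def consensus_mask(
    mm: MatchMatrix, obj: Mapping[str, int], annsets: Sequence[ReaderAnnotationSet]
) -> frozenset:
    """Representative mask of a consensus object: the medoid member call.

    The medoid is the member with the highest mean pairwise overlap (per
    the matrix's metric kind) to the other members; singletons use their
    own mask.  Ties break toward the reader order of the match matrix.
    A real instance boundary is preserved rather than fabricating pixels
    by voting.
    """
    by_reader = {s.reader_id: s for s in annsets}
    members = [
        by_reader[reader].calls(mm.image_id)[idx]
        for reader, idx in sorted(obj.items(), key=lambda kv: mm.readers.index(kv[0]))
    ]
    if len(members) == 1:
        call = members[0]
    else:
        means = []
        for a in members:
            vals = [call_score(a, b, mm.metric_kind) for b in members if b is not a]
            means.append(sum(vals) / len(vals))
        call = members[int(np.argmax(means))]  # argmax keeps first on ties
    if call.mask is None:
        raise ValueError("consensus mask requires calls with masks")
    return call.mask


@dataclass
class LayeredConsensus:
    """Stack of N_R label images; layer k holds objects called by exactly k readers.

    Labels (1..n per layer), not binary masks, are stored so adjacent
    objects remain separable even when tightly packed.
    """

    image_id: str
    layers: np.ndarray  # (N_R, H, W) integer labels

    @property
    def n_layers(self) -> int:
        return int(self.layers.shape[0])

    def objects_in_layer(self, k: int) -> int:
        """Number of objects in layer k (1-based)."""
        return int(self.layers[k - 1].max())


def layered_representation(
    mm: MatchMatrix,
    annsets: Sequence[ReaderAnnotationSet],
    dims: tuple[int, int] | None = None,
) -> LayeredConsensus:
    """Render the match matrix as an N_R-layer label stack."""
    by_reader = {s.reader_id: s for s in annsets}
    recorded = {
        tuple(by_reader[r].image_dims[mm.image_id])
        for r in mm.readers
        if mm.image_id in by_reader[r].image_dims
    }
    if dims is None:
        if len(recorded) != 1:
            raise ValueError(f"ambiguous image dims {recorded} for {mm.image_id!r}")
        dims = next(iter(recorded))
    elif recorded and tuple(dims) not in recorded:
        raise ValueError(f"dims {dims} do not match annotation dims {recorded}")
    h, w = dims
    n_r = len(mm.readers)
    layers = np.zeros((n_r, h, w), dtype=np.int32)
    counters = [0] * n_r
    for obj in mm.objects:
        k = len(obj)
        counters[k - 1] += 1
        label = counters[k - 1]
        mask = consensus_mask(mm, obj, annsets)
        rr, cc = zip(*mask)
        layers[k - 1, list(rr), list(cc)] = label
    return LayeredConsensus(image_id=mm.image_id, layers=layers)


def curate_ground_truth(
    mm: MatchMatrix,
    annsets: Sequence[ReaderAnnotationSet],
    min_calls: int,
    reader_id: str | None = None,
) -> ReaderAnnotationSet:
    """Curated ground truth: consensus masks of objects called by >= min_calls readers.

    Returns a synthetic "reader" whose calls are the representative
    masks of the retained objects; raising ``min_calls`` raises the
    stringency of the curated set, from any-single-reader (1) to
    unanimous (N_R).
    """
    n_r = len(mm.readers)
    if not (1 <= min_calls <= n_r):
        raise ValueError(f"min_calls must be in 1..{n_r}, got {min_calls}")
    if reader_id is None:
        reader_id = f"consensus_min{min_calls}"
    by_reader = {s.reader_id: s for s in annsets}
    dims = by_reader[mm.readers[0]].image_dims[mm.image_id]
    out = ReaderAnnotationSet(reader_id=reader_id, image_dims={mm.image_id: dims})
    calls = []
    for obj in mm.objects_with_min_calls(min_calls):
        mask = consensus_mask(mm, obj, annsets)
        calls.append(
            Call(
                reader_id=reader_id,
                image_id=mm.image_id,
                call_index=len(calls),
                mask=mask,
            )
        )
    out.images[mm.image_id] = calls
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_match_matrix_json(mm: MatchMatrix, path: str | Path) -> None:
    doc = {
        "image_id": mm.image_id,
        "readers": list(mm.readers),
        "metric_kind": mm.metric_kind,
        "threshold": mm.threshold,
        "objects": [dict(o) for o in mm.objects],
        "dropped_edges": [
            {"a": list(u), "b": list(v), "score": s} for u, v, s in mm.dropped_edges
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_match_matrix_json(path: str | Path) -> MatchMatrix:
    doc = json.loads(Path(path).read_text())
    return MatchMatrix(
        image_id=doc["image_id"],
        readers=tuple(doc["readers"]),
        objects=[{str(r): int(i) for r, i in o.items()} for o in doc["objects"]],
        metric_kind=doc.get("metric_kind", "mask_iou"),
        threshold=float(doc.get("threshold", 0.5)),
        dropped_edges=[
            ((e["a"][0], int(e["a"][1])), (e["b"][0], int(e["b"][1])), float(e["score"]))
            for e in doc.get("dropped_edges", [])
        ],
    )


def write_layered_tiff(lc: LayeredConsensus, path: str | Path) -> None:
    """Write the layered consensus as a multi-page TIFF, one page per k."""
    import tifffile

    tifffile.imwrite(path, lc.layers.astype(np.int32), photometric="minisblack")
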