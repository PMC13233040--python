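"""Data model and I/O for multireader instance annotations.

A *call* is one putative object delineated by one reader on one image.
Calls carry a pixel mask (a set of ``(row, col)`` coordinates), an
inclusive bounding box ``(xmin, ymin, xmax, ymax)`` with ``x = col`` and
``y = row``, or both.  Readers' calls are grouped per image into
:class:`ReaderAnnotationSet` containers, which every downstream stage
(agreement matrices, consensus, metrics) consumes.

Two interchange formats are supported:

* **Label images** — single-channel integer TIFF/PNG, 0 = background,
  each positive label one call.  Label images cannot express calls from
  the same reader that overlap.
* **Instance JSON** — a documented schema with per-call polygons,
  run-length encodings, or bounding boxes.  Overlapping same-reader
  calls are representable and preserved.

Coordinate convention throughout: row-major 0-based pixel grid; bounding
boxes are inclusive at both ends, so a box has area
``(xmax - xmin + 1) * (ymax - ymin + 1)``.  Pixel ``(r, c)`` occupies the
unit square ``[c, c+1] x [r, r+1]`` in continuous polygon coordinates and
is rasterized as foreground when its center ``(c + 0.5, r + 0.5)`` lies
inside or on the polygon boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Call",
    "ReaderAnnotationSet",
    "MetricRecord",
    "AnnotationError",
    "tight_bbox",
    "load_label_images",
    "load_instance_json",
    "extract_bounding_boxes",
    "write_metric_table",
    "read_metric_table",
]

Pixel = tuple[int, int]
BBox = tuple[int, int, int, int]


class AnnotationError(ValueError):
    """Raised for malformed annotation inputs (bad files, schema violations)."""


def tight_bbox(mask: Iterable[Pixel]) -> BBox:
    """Inclusive ``(xmin, ymin, xmax, ymax)`` bounds of a pixel set (x=col, y=row)."""
    rows, cols = zip(*mask)
    return (min(cols), min(rows), max(cols), max(rows))


@dataclass(frozen=True)
class Call:
    """One putative object called by one reader on one image.

    At least one of ``mask`` / ``bbox`` must be present; when both are,
    the bbox must be the tight inclusive bound of the mask.
    """

    reader_id: str
    image_id: str
    call_index: int
    mask: frozenset[Pixel] | None = None
    bbox: BBox | None = None

    def __post_init__(self) -> None:
        if self.call_index < 0:
            raise AnnotationError(f"call_index must be >= 0, got {self.call_index}")
        if self.mask is None and self.bbox is None:
            raise AnnotationError(
                f"call {self.reader_id}/{self.image_id}/{self.call_index}: "
                "needs a mask or a bbox"
            )
        if self.mask is not None:
            if not isinstance(self.mask, frozenset):
                object.__setattr__(self, "mask", frozenset(self.mask))
            if not self.mask:
                raise AnnotationError(
                    f"call {self.reader_id}/{self.image_id}/{self.call_index}: empty mask"
                )
        if self.bbox is not None:
            xmin, ymin, xmax, ymax = self.bbox
            if xmin > xmax or ymin > ymax:
                raise AnnotationError(f"malformed bbox {self.bbox}")
            if self.mask is not None and tuple(self.bbox) != tight_bbox(self.mask):
                raise AnnotationError(
                    f"bbox {self.bbox} is not the tight bound of the mask "
                    f"({tight_bbox(self.mask)})"
                )

    def with_tight_bbox(self) -> "Call":
        """Copy of this call with ``bbox`` set to the tight bound of its mask."""
        if self.mask is None:
            raise AnnotationError(
                f"call {self.reader_id}/{self.image_id}/{self.call_index}: "
                "cannot derive a bbox without a mask"
            )
        return replace(self, bbox=tight_bbox(self.mask))

    @property
    def n_pixels(self) -> int:
        if self.mask is None:
            raise AnnotationError("call has no mask")
        return len(self.mask)


@dataclass
class ReaderAnnotationSet:
    """All calls by one reader over a collection of images."""

    reader_id: str
    images: dict[str, list[Call]] = field(default_factory=dict)
    image_dims: dict[str, tuple[int, int]] = field(default_factory=dict)

    def validate(self) -> None:
        """Check index contiguity and that every pixel lies inside the image."""
        for image_id, calls in self.images.items():
            if image_id not in self.image_dims:
                raise AnnotationError(f"no dims recorded for image {image_id!r}")
            h, w = self.image_dims[image_id]
            indices = [c.call_index for c in calls]
            if indices != list(range(len(calls))):
                raise AnnotationError(
                    f"reader {self.reader_id!r}, image {image_id!r}: call indices "
                    f"{indices} are not contiguous 0..n-1"
                )
            for c in calls:
                if c.reader_id != self.reader_id or c.image_id != image_id:
                    raise AnnotationError(
                        f"call {c.call_index} mislabeled ({c.reader_id}/{c.image_id})"
                    )
                if c.mask is not None:
                    for r, col in c.mask:
                        if not (0 <= r < h and 0 <= col < w):
                            raise AnnotationError(
                                f"reader {self.reader_id!r}, image {image_id!r}, call "
                                f"{c.call_index}: pixel ({r},{col}) outside {h}x{w}"
                            )
                else:
                    xmin, ymin, xmax, ymax = c.bbox  # type: ignore[misc]
                    if xmin < 0 or ymin < 0 or xmax >= w or ymax >= h:
                        raise AnnotationError(
                            f"reader {self.reader_id!r}, image {image_id!r}, call "
                            f"{c.call_index}: bbox {c.bbox} outside {h}x{w}"
                        )

    def calls(self, image_id: str) -> list[Call]:
        return self.images.get(image_id, [])

    def n_calls(self, image_id: str) -> int:
        return len(self.images.get(image_id, []))


_METRIC_NAMES = {"jaccard", "sorensen", "multireader_jaccard", "multireader_sorensen"}


@dataclass(frozen=True)
class MetricRecord:
    """One row of a metric table: a (possibly undefined) index value.

    ``value is None`` marks an undefined metric (no calls by any reader
    in the group); undefined values are excluded from aggregation and
    written as empty CSV cells, never as 0 or "nan" text.
    """

    image_id: str
    metric_name: str
    iou_threshold: float
    reader_group: tuple[str, ...]
    value: float | None

    def __post_init__(self) -> None:
        if self.metric_name not in _METRIC_NAMES:
            raise AnnotationError(f"unknown metric_name {self.metric_name!r}")
        if not (0.0 < self.iou_threshold <= 1.0):
            raise AnnotationError(f"iou_threshold must be in (0,1], got {self.iou_threshold}")
        if self.value is not None and not (0.0 <= self.value <= 1.0):
            raise AnnotationError(f"metric value {self.value} outside [0,1]")
        object.__setattr__(self, "reader_group", tuple(self.reader_group))


# ---------------------------------------------------------------------------
# label-image input
# ---------------------------------------------------------------------------


def _read_label_array(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    return np.asarray(arr)


def _calls_from_label_array(
    arr: np.ndarray, reader_id: str, image_id: str, origin: str
) -> list[Call]:
    if arr.ndim != 2:
        raise AnnotationError(f"{origin}: expected a 2-D label image, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise AnnotationError(f"{origin}: label image must be integer-typed, got {arr.dtype}")
    if arr.size and arr.min() < 0:
        raise AnnotationError(f"{origin}: negative labels are not allowed")
    calls = []
    for idx, label in enumerate(np.unique(arr[arr > 0])):
        rr, cc = np.nonzero(arr == label)
        mask = frozenset(zip(rr.tolist(), cc.tolist()))
        calls.append(Call(reader_id=reader_id, image_id=image_id, call_index=idx, mask=mask))
    return calls


def load_label_images(
    paths: Mapping[str, Mapping[str, str | Path]],
    dims: Mapping[str, tuple[int, int]] | None = None,
) -> list[ReaderAnnotationSet]:
    """Load per-reader label images into annotation sets.

    Parameters
    ----------
    paths
        ``{reader_id: {image_id: path}}``.  Each file must be a 2-D
        integer label image with 0 background; each distinct positive
        label becomes one call, indexed in ascending label order.
    dims
        Optional expected ``{image_id: (height, width)}``; a mismatch
        with the file on disk is an error naming the offending file.
    """
    annsets = []
    seen_dims: dict[str, tuple[int, int]] = dict(dims or {})
    for reader_id, by_image in paths.items():
        annset = ReaderAnnotationSet(reader_id=reader_id)
        for image_id, path in by_image.items():
            arr = _read_label_array(path)
            if arr.ndim != 2:
                raise AnnotationError(f"{path}: expected a 2-D label image, got shape {arr.shape}")
            if image_id in seen_dims and tuple(arr.shape) != tuple(seen_dims[image_id]):
                raise AnnotationError(
                    f"{path}: dims {arr.shape} do not match expected "
                    f"{seen_dims[image_id]} for image {image_id!r}"
                )
            seen_dims.setdefault(image_id, (int(arr.shape[0]), int(arr.shape[1])))
            annset.images[image_id] = _calls_from_label_array(
                arr, reader_id, image_id, origin=str(path)
            )
            annset.image_dims[image_id] = seen_dims[image_id]
        annset.validate()
        annsets.append(annset)
    return annsets


def annset_to_label_array(
    annset: ReaderAnnotationSet, image_id: str, dtype=np.int32
) -> np.ndarray:
    """Render one reader's calls on one image as a label image.

    Calls are painted in ascending ``call_index`` order with labels
    ``index + 1``; overlapping same-reader calls (possible via JSON
    input) are flattened with later calls painting over earlier ones, so
    this rendering is lossy for overlapping inputs.
    """
    h, w = annset.image_dims[image_id]
    out = np.zeros((h, w), dtype=dtype)
    for call in annset.calls(image_id):
        if call.mask is None:
            raise AnnotationError(f"call {call.call_index} has no mask to render")
        rr, cc = zip(*call.mask)
        out[list(rr), list(cc)] = call.call_index + 1
    return out


# ---------------------------------------------------------------------------
# instance-JSON input
# ---------------------------------------------------------------------------


def _rasterize_polygon(vertices: Sequence[Sequence[float]], h: int, w: int) -> frozenset[Pixel]:
    # pixel (r,c) is foreground iff its center (c+.5, r+.5) is inside or on
    # the polygon boundary
    import shapely

    poly = shapely.Polygon([(float(x), float(y)) for x, y in vertices])
    if not poly.is_valid:
        poly = poly.buffer(0)
    xmin, ymin, xmax, ymax = poly.bounds
    r0, r1 = max(0, int(np.floor(ymin - 0.5))), min(h - 1, int(np.ceil(ymax)))
    c0, c1 = max(0, int(np.floor(xmin - 0.5))), min(w - 1, int(np.ceil(xmax)))
    if r1 < r0 or c1 < c0:
        return frozenset()
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    # point intersects == point covered (interior or boundary)
    hits = shapely.intersects_xy(poly, cc.ravel() + 0.5, rr.ravel() + 0.5)
    return frozenset(zip(rr.ravel()[hits].tolist(), cc.ravel()[hits].tolist()))


def _decode_rle(counts: Sequence[int], h: int, w: int, origin: str) -> frozenset[Pixel]:
    # row-major alternating run lengths, starting with background
    if sum(counts) != h * w:
        raise AnnotationError(f"{origin}: RLE counts sum to {sum(counts)}, expected {h * w}")
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    fg = False
    for run in counts:
        if run < 0:
            raise AnnotationError(f"{origin}: negative RLE run")
        if fg:
            flat[pos : pos + run] = True
        pos += run
        fg = not fg
    rr, cc = np.nonzero(flat.reshape(h, w))
    return frozenset(zip(rr.tolist(), cc.tolist()))


def load_instance_json(path: str | Path) -> list[ReaderAnnotationSet]:
    """Load annotation sets from the instance-JSON interchange format.

    Schema (one reader object, or a JSON array of them)::

        {"reader_id": str,
         "images": [{"image_id": str, "height": int, "width": int,
                     "calls": [{"index": int,
                                "polygon": [[x, y], ...]   # pixel corners
                                | "rle": [int, ...]        # row-major, bg first
                                | "bbox": [xmin, ymin, xmax, ymax]}]}]}

    Polygons are rasterized with the pixel-center rule; overlapping
    calls from the same reader are preserved as distinct calls.
    Schema violations raise :class:`AnnotationError` naming the JSON
    path of the violation.
    """
    with open(path) as fh:
        doc = json.load(fh)
    readers = doc if isinstance(doc, list) else [doc]
    annsets = []
    for ri, rdoc in enumerate(readers):
        where = f"$[{ri}]"
        if not isinstance(rdoc, dict) or "reader_id" not in rdoc:
            raise AnnotationError(f"{where}: expected an object with 'reader_id'")
        annset = ReaderAnnotationSet(reader_id=str(rdoc["reader_id"]))
        for ii, idoc in enumerate(rdoc.get("images", [])):
            iwhere = f"{where}.images[{ii}]"
            for key in ("image_id", "height", "width"):
                if key not in idoc:
                    raise AnnotationError(f"{iwhere}: missing {key!r}")
            image_id = str(idoc["image_id"])
            h, w = int(idoc["height"]), int(idoc["width"])
            if image_id in annset.images:
                raise AnnotationError(f"{iwhere}: duplicate image_id {image_id!r}")
            calls: list[Call] = []
            seen_idx: set[int] = set()
            for ci, cdoc in enumerate(idoc.get("calls", [])):
                cwhere = f"{iwhere}.calls[{ci}]"
                idx = cdoc.get("index", ci)
                if idx in seen_idx:
                    raise AnnotationError(f"{cwhere}: duplicate call index {idx}")
                seen_idx.add(idx)
                mask = None
                bbox = None
                if "polygon" in cdoc:
                    mask = _rasterize_polygon(cdoc["polygon"], h, w)
                    if not mask:
                        raise AnnotationError(f"{cwhere}: polygon covers no pixel centers")
                elif "rle" in cdoc:
                    mask = _decode_rle(cdoc["rle"], h, w, origin=cwhere)
                    if not mask:
                        raise AnnotationError(f"{cwhere}: RLE encodes an empty mask")
                elif "bbox" in cdoc:
                    bbox = tuple(int(v) for v in cdoc["bbox"])
                    if len(bbox) != 4:
                        raise AnnotationError(f"{cwhere}: bbox must have 4 entries")
                else:
                    raise AnnotationError(f"{cwhere}: needs polygon, rle, or bbox")
                calls.append(
                    Call(
                        reader_id=annset.reader_id,
                        image_id=image_id,
                        call_index=int(idx),
                        mask=mask,
                        bbox=bbox,
                    )
                )
            calls.sort(key=lambda c: c.call_index)
            if [c.call_index for c in calls] != list(range(len(calls))):
                raise AnnotationError(f"{iwhere}: call indices are not contiguous 0..n-1")
            annset.images[image_id] = calls
            annset.image_dims[image_id] = (h, w)
        annset.validate()
        annsets.append(annset)
    return annsets


def extract_bounding_boxes(annset: ReaderAnnotationSet) -> ReaderAnnotationSet:
    """Copy of ``annset`` with every call's bbox set to its mask's tight bound.

    This is the reduction used to compare instance segmentations with a
    box-only object detector: boxes are the min/max x and y coordinates
    of each object's mask.  Masks are retained.
    """
    out = ReaderAnnotationSet(reader_id=annset.reader_id, image_dims=dict(annset.image_dims))
    for image_id, calls in annset.images.items():
        out.images[image_id] = [c.with_tight_bbox() for c in calls]
    return out


# ---------------------------------------------------------------------------
# metric tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["image_id", "metric_name", "iou_threshold", "reader_group", "value"]


def write_metric_table(records: Sequence[MetricRecord], path: str | Path) -> None:
    """Write metric records as CSV; undefined values become empty cells."""
    if not records:
        raise AnnotationError("no records to write")
    df = pd.DataFrame(
        {
            "image_id": [r.image_id for r in records],
            "metric_name": [r.metric_name for r in records],
            "iou_threshold": [r.iou_threshold for r in records],
            "reader_group": [";".join(r.reader_group) for r in records],
            "value": [r.value for r in records],
        },
        columns=_TABLE_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_metric_table(path: str | Path) -> list[MetricRecord]:
    """Read back a CSV written by :func:`write_metric_table`."""
    df = pd.read_csv(path, dtype={"image_id": str, "metric_name": str, "reader_group": str})
    records = []
    for row in df.itertuples(index=False):
        value = None if pd.isna(row.value) else float(row.value)
        records.append(
            MetricRecord(
                image_id=row.image_id,
                metric_name=row.metric_name,
                iou_threshold=float(row.iou_threshold),
                reader_group=tuple(str(row.reader_group).split(";")),
                value=value,
            )
        )
    return records
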