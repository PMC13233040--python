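"""Call/annotation-set data model and the label-image / JSON / CSV formats."""

from __future__ import annotations

import json

import numpy as np
import pytest
import tifffile

from mragree.annotations import (
    AnnotationError,
    Call,
    MetricRecord,
    ReaderAnnotationSet,
    annset_to_label_array,
    extract_bounding_boxes,
    load_instance_json,
    load_label_images,
    read_metric_table,
    tight_bbox,
    write_metric_table,
)
from tests.conftest import make_annset, make_call, square


class TestCallInvariants:
    def test_needs_mask_or_bbox(self):
        with pytest.raises(AnnotationError):
            Call("A", "img", 0)

    def test_empty_mask_rejected(self):
        with pytest.raises(AnnotationError):
            Call("A", "img", 0, mask=frozenset())

    def test_bbox_must_be_tight_when_both_given(self):
        mask = frozenset({(0, 0), (2, 3)})
        Call("A", "img", 0, mask=mask, bbox=(0, 0, 3, 2))  # ok
        with pytest.raises(AnnotationError):
            Call("A", "img", 0, mask=mask, bbox=(0, 0, 5, 5))

    def test_tight_bbox_convention(self):
        # x = column, y = row; single pixel (row 5, col 7) -> (7,5,7,5)
        assert tight_bbox({(0, 0), (2, 3)}) == (0, 0, 3, 2)
        assert tight_bbox({(5, 7)}) == (7, 5, 7, 5)


class TestExtractBoundingBoxes:
    def test_boxes_are_tight_and_masks_retained(self):
        annset = make_annset("A", {"img": [square(2, 3, 4), {(5, 7)}]}, (16, 16))
        out = extract_bounding_boxes(annset)
        assert out.images["img"][0].bbox == (3, 2, 6, 5)
        assert out.images["img"][1].bbox == (7, 5, 7, 5)
        assert out.images["img"][0].mask == annset.images["img"][0].mask

    def test_idempotent(self):
        annset = make_annset("A", {"img": [square(0, 0, 3)]}, (8, 8))
        once = extract_bounding_boxes(annset)
        twice = extract_bounding_boxes(once)
        assert once.images["img"] == twice.images["img"]

    def test_maskless_call_rejected(self):
        annset = ReaderAnnotationSet("A", image_dims={"img": (8, 8)})
        annset.images["img"] = [make_call("A", "img", 0, bbox=(0, 0, 2, 2))]
        with pytest.raises(AnnotationError):
            extract_bounding_boxes(annset)


class TestLabelImages:
    def test_labels_become_calls_in_label_order(self, tmp_path):
        arr = np.zeros((4, 4), dtype=np.int32)
        arr[0, 0] = 1
        arr[0, 1] = 1
        arr[3, 3] = 3
        path = tmp_path / "r1" / "img.tif"
        path.parent.mkdir()
        tifffile.imwrite(path, arr)
        (annset,) = load_label_images({"r1": {"img": path}})
        calls = annset.images["img"]
        assert [c.call_index for c in calls] == [0, 1]
        assert calls[0].mask == frozenset({(0, 0), (0, 1)})
        assert calls[1].mask == frozenset({(3, 3)})

    def test_all_zero_image_yields_no_calls(self, tmp_path):
        tifffile.imwrite(tmp_path / "img.tif", np.zeros((4, 4), dtype=np.int32))
        (annset,) = load_label_images({"r1": {"img": tmp_path / "img.tif"}})
        assert annset.images["img"] == []

    def test_two_readers_share_dims(self, tmp_path):
        for reader in ("r1", "r2"):
            (tmp_path / reader).mkdir()
            arr = np.zeros((6, 5), dtype=np.int32)
            arr[1, 1] = 1
            tifffile.imwrite(tmp_path / reader / "img.tif", arr)
        annsets = load_label_images(
            {r: {"img": tmp_path / r / "img.tif"} for r in ("r1", "r2")}
        )
        assert [a.image_dims["img"] for a in annsets] == [(6, 5), (6, 5)]

    def test_bad_inputs_name_the_file(self, tmp_path):
        tifffile.imwrite(tmp_path / "neg.tif", np.full((3, 3), -2, dtype=np.int32))
        with pytest.raises(AnnotationError, match="neg.tif"):
            load_label_images({"r": {"img": tmp_path / "neg.tif"}})
        tifffile.imwrite(tmp_path / "3d.tif", np.zeros((2, 3, 3), dtype=np.int32))
        with pytest.raises(AnnotationError, match="3d.tif"):
            load_label_images({"r": {"img": tmp_path / "3d.tif"}})
        tifffile.imwrite(tmp_path / "ok.tif", np.zeros((3, 3), dtype=np.int32))
        with pytest.raises(AnnotationError, match="ok.tif"):
            load_label_images({"r": {"img": tmp_path / "ok.tif"}}, dims={"img": (4, 4)})

    def test_roundtrip_preserves_partition(self, tmp_path):
        rng = np.random.default_rng(5)
        arr = np.zeros((16, 16), dtype=np.int32)
        arr[2:5, 2:5] = 4
        arr[9:12, 9:14] = 7
        tifffile.imwrite(tmp_path / "img.tif", arr)
        (annset,) = load_label_images({"r": {"img": tmp_path / "img.tif"}})
        back = annset_to_label_array(annset, "img")
        # identical partition up to label renumbering
        assert set(map(frozenset, [set(zip(*np.nonzero(arr == l))) for l in (4, 7)])) == set(
            map(frozenset, [set(zip(*np.nonzero(back == l))) for l in (1, 2)])
        )


class TestInstanceJson:
    def _write(self, tmp_path, doc):
        path = tmp_path / "ann.json"
        path.write_text(json.dumps(doc))
        return path

    def test_bbox_only_record(self, tmp_path):
        doc = {
            "reader_id": "r1",
            "images": [
                {"image_id": "img", "height": 8, "width": 8,
                 "calls": [{"index": 0, "bbox": [1, 2, 3, 4]}]}
            ],
        }
        (annset,) = load_instance_json(self._write(tmp_path, doc))
        call = annset.images["img"][0]
        assert call.mask is None and call.bbox == (1, 2, 3, 4)

    def test_unit_square_polygon_rasterization(self, tmp_path):
        # corners (0,0)-(1,1): only pixel (0,0) has its center inside
        doc = {
            "reader_id": "r1",
            "images": [
                {"image_id": "img", "height": 4, "width": 4,
                 "calls": [{"index": 0, "polygon": [[0, 0], [1, 0], [1, 1], [0, 1]]}]}
            ],
        }
        (annset,) = load_instance_json(self._write(tmp_path, doc))
        assert annset.images["img"][0].mask == frozenset({(0, 0)})

    def test_polygon_matches_point_in_polygon_oracle(self, tmp_path):
        # independent oracle: matplotlib's point-in-polygon test on pixel centers
        from matplotlib.path import Path as MplPath

        poly = [[0.5, 0.5], [6.2, 1.0], [5.5, 6.4], [1.2, 5.0]]
        doc = {
            "reader_id": "r1",
            "images": [
                {"image_id": "img", "height": 8, "width": 8,
                 "calls": [{"index": 0, "polygon": poly}]}
            ],
        }
        (annset,) = load_instance_json(self._write(tmp_path, doc))
        path = MplPath(np.array(poly))
        expected = {
            (r, c)
            for r in range(8)
            for c in range(8)
            if path.contains_point((c + 0.5, r + 0.5), radius=1e-9)
        }
        assert annset.images["img"][0].mask == frozenset(expected)

    def test_rle_row_major_background_first(self, tmp_path):
        # 2x3 grid: 1 bg, 2 fg, 3 bg -> pixels (0,1),(0,2)
        doc = {
            "reader_id": "r1",
            "images": [
                {"image_id": "img", "height": 2, "width": 3,
                 "calls": [{"index": 0, "rle": [1, 2, 3]}]}
            ],
        }
        (annset,) = load_instance_json(self._write(tmp_path, doc))
        assert annset.images["img"][0].mask == frozenset({(0, 1), (0, 2)})

    def test_duplicate_call_index_rejected_with_json_path(self, tmp_path):
        doc = {
            "reader_id": "r1",
            "images": [
                {"image_id": "img", "height": 4, "width": 4,
                 "calls": [{"index": 0, "bbox": [0, 0, 1, 1]},
                           {"index": 0, "bbox": [2, 2, 3, 3]}]}
            ],
        }
        with pytest.raises(AnnotationError, match=r"calls\[1\]"):
            load_instance_json(self._write(tmp_path, doc))

    def test_overlapping_same_reader_calls_preserved(self, tmp_path):
        doc = {
            "reader_id": "r1",
            "images": [
                {"image_id": "img", "height": 6, "width": 6,
                 "calls": [{"index": 0, "rle": [0, 12, 24]},
                           {"index": 1, "rle": [6, 12, 18]}]}
            ],
        }
        (annset,) = load_instance_json(self._write(tmp_path, doc))
        m0, m1 = (c.mask for c in annset.images["img"])
        assert m0 & m1  # label images could not encode this overlap

    def test_json_and_label_image_loads_agree(self, tmp_path):
        # same two blobs through both input routes -> identical pixel sets
        arr = np.zeros((6, 6), dtype=np.int32)
        arr[1:3, 1:3] = 1
        arr[4, 4] = 2
        tifffile.imwrite(tmp_path / "img.tif", arr)
        (from_labels,) = load_label_images({"r1": {"img": tmp_path / "img.tif"}})

        def rle_of(mask):
            flat = np.zeros(36, dtype=bool)
            for r, c in mask:
                flat[r * 6 + c] = True
            runs, prev, count = [], False, 0
            for v in flat:
                if v == prev:
                    count += 1
                else:
                    runs.append(count)
                    prev, count = v, 1
            runs.append(count)
            return runs

        doc = {
            "reader_id": "r1",
            "images": [
                {"image_id": "img", "height": 6, "width": 6,
                 "calls": [
                     {"index": i, "rle": rle_of(c.mask)}
                     for i, c in enumerate(from_labels.images["img"])
                 ]}
            ],
        }
        (from_json,) = load_instance_json(self._write(tmp_path, doc))
        assert [c.mask for c in from_json.images["img"]] == [
            c.mask for c in from_labels.images["img"]
        ]


class TestMetricTable:
    def test_roundtrip_including_undefined(self, tmp_path):
        records = [
            MetricRecord("img0", "jaccard", 0.5, ("A", "B"), 0.375),
            MetricRecord("img1", "multireader_jaccard", 0.25, ("A", "B", "C"), None),
            MetricRecord("img2", "sorensen", 0.75, ("A", "B"), 1.0),
        ]
        path = tmp_path / "metrics.csv"
        write_metric_table(records, path)
        assert read_metric_table(path) == records

    def test_undefined_written_as_empty_cell(self, tmp_path):
        path = tmp_path / "metrics.csv"
        write_metric_table(
            [MetricRecord("img", "jaccard", 0.5, ("A", "B"), None)], path
        )
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2
        assert lines[1].endswith(",")
        assert "nan" not in lines[1].lower()

    def test_empty_record_list_rejected(self, tmp_path):
        with pytest.raises(AnnotationError):
            write_metric_table([], tmp_path / "x.csv")

    def test_value_range_enforced(self):
        with pytest.raises(AnnotationError):
            MetricRecord("img", "jaccard", 0.5, ("A",), 1.5)
        with pytest.raises(AnnotationError):
            MetricRecord("img", "jaccard", 0.0, ("A",), 0.5)
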