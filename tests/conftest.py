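from __future__ import annotations

import numpy as np
import pytest

from mragree.annotations import Call, ReaderAnnotationSet


def make_call(reader_id, image_id, call_index, pixels=None, bbox=None):
    mask = frozenset(pixels) if pixels is not None else None
    return Call(
        reader_id=reader_id, image_id=image_id, call_index=call_index, mask=mask, bbox=bbox
    )


def make_annset(reader_id, masks_by_image, dims):
    """Build a ReaderAnnotationSet from {image_id: [pixel-set, ...]}."""
    annset = ReaderAnnotationSet(reader_id=reader_id)
    for image_id, masks in masks_by_image.items():
        annset.images[image_id] = [
            make_call(reader_id, image_id, i, pixels=m) for i, m in enumerate(masks)
        ]
        annset.image_dims[image_id] = dims
    annset.validate()
    return annset


def square(r0, c0, size):
    return {(r, c) for r in range(r0, r0 + size) for c in range(c0, c0 + size)}


@pytest.fixture(scope="session")
def small_cohort():
    """5 moderate readers on 8 small images; shared across read-only tests."""
    from mragree.simulate import generate_cohort

    return generate_cohort(8, 5, seed=42, dims=(128, 128), n_objects=6)


@pytest.fixture(scope="session")
def three_reader_fixture():
    """A, B agree on two objects; C has two calls disjoint from everyone."""
    dims = (32, 32)
    a = make_annset("A", {"img": [square(2, 2, 4), square(10, 10, 4)]}, dims)
    b = make_annset("B", {"img": [square(2, 2, 4), square(10, 10, 4)]}, dims)
    c = make_annset("C", {"img": [square(20, 20, 4), square(26, 2, 4)]}, dims)
    return [a, b, c]
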