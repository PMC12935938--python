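"""Annotation rasterization, resizing, and per-region dataset splitting."""

import json

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from canopyseg.coverage import group_coverage, instance_coverage
from canopyseg.dataio import (
    AnnotationError,
    PolygonAnnotation,
    SplitPlan,
    labelme_to_mask,
    load_mask,
    rasterize_polygon,
    read_labelme,
    resize_pair,
    save_mask,
    split_dataset,
)


def test_axis_aligned_square_rasterization():
    ann = PolygonAnnotation((10, 10), [("plant", np.array([(0, 0), (5, 0), (5, 5), (0, 5)]))])
    mask = labelme_to_mask(ann)
    assert int(mask.sum()) == 25
    assert mask[:5, :5].all() and not mask[5:, :].any() and not mask[:, 5:].any()


def test_empty_annotation_and_disjoint_squares():
    assert labelme_to_mask(PolygonAnnotation((8, 8), [])).sum() == 0
    ann = PolygonAnnotation(
        (12, 12),
        [
            ("plant", np.array([(1, 1), (4, 1), (4, 4), (1, 4)])),
            ("plant", np.array([(7, 7), (11, 7), (11, 11), (7, 11)])),
        ],
    )
    assert len(instance_coverage(labelme_to_mask(ann))) == 2


def test_degenerate_polygon_names_index():
    ann = PolygonAnnotation((5, 5), [("plant", np.array([(0, 0), (1, 1)]))])
    with pytest.raises(AnnotationError, match="polygon 0"):
        labelme_to_mask(ann)


def test_non_plant_labels_ignored():
    ann = PolygonAnnotation((6, 6), [("tray", np.array([(0, 0), (6, 0), (6, 6), (0, 6)]))])
    assert labelme_to_mask(ann).sum() == 0


def test_rasterizer_matches_point_in_polygon_oracle(rng):
    """50 random rectangles (some rotated): pixel-center membership via shapely."""
    for _ in range(50):
        w, h = rng.uniform(2, 12, size=2)
        cx, cy = rng.uniform(4, 12, size=2)
        theta = rng.uniform(0, np.pi / 2)
        corners = []
        for sx, sy in ((-1, -1), (1, -1), (1, 1), (-1, 1)):
            x = cx + (sx * w / 2) * np.cos(theta) - (sy * h / 2) * np.sin(theta)
            y = cy + (sx * w / 2) * np.sin(theta) + (sy * h / 2) * np.cos(theta)
            corners.append((x, y))
        mask = rasterize_polygon(np.array(corners), (16, 16))
        poly = Polygon(corners)
        for i in range(16):
            for j in range(16):
                inside = poly.contains(Point(j + 0.5, i + 0.5))
                assert bool(mask[i, j]) == inside, (corners, i, j)


def test_rasterize_then_measure_group_coverage():
    ann = PolygonAnnotation((20, 20), [("plant", np.array([(0, 0), (10, 0), (10, 20), (0, 20)]))])
    assert group_coverage(labelme_to_mask(ann)) == 0.5


def test_read_labelme_round_trip(tmp_path):
    doc = {
        "imageHeight": 9,
        "imageWidth": 7,
        "shapes": [{"label": "plant", "points": [[1, 1], [5, 1], [5, 5], [1, 5]]}],
    }
    p = tmp_path / "ann.json"
    p.write_text(json.dumps(doc))
    ann = read_labelme(p)
    assert ann.image_size == (9, 7)
    assert labelme_to_mask(ann).sum() == 16


def test_resize_pair_contracts(rng):
    img = (rng.random((320, 320, 3)) * 255).astype(np.uint8)
    mask = np.ones((320, 320), dtype=np.uint8)
    img2, mask2 = resize_pair(img, mask, 640)
    assert img2.shape == (640, 640, 3) and mask2.shape == (640, 640)
    assert group_coverage(mask2) == 1.0  # nearest preserves constants
    checker = np.indices((10, 10)).sum(axis=0) % 2
    _, up = resize_pair(np.zeros((10, 10, 3), dtype=np.uint8), checker.astype(np.uint8), 40)
    assert set(np.unique(up)) <= {0, 1}
    same_img, same_mask = resize_pair(img[:, :320], mask, 320)
    assert same_img is img or np.array_equal(same_img, img)
    with pytest.raises(ValueError, match="spatial"):
        resize_pair(img, mask[:100], 64)


def test_split_sizes_match_acquisition_design():
    regions = [[f"cq_{i}" for i in range(500)], [f"bj_{i}" for i in range(500)]]
    tr, va, te = split_dataset(regions, SplitPlan(ratio=(6, 2, 2), seed=3))
    assert (len(tr), len(va), len(te)) == (600, 200, 200)


def test_split_partition_and_determinism():
    regions = [list(range(10)), list(range(100, 107))]
    plan = SplitPlan(ratio=(6, 2, 2), seed=5)
    tr, va, te = split_dataset(regions, plan)
    again = split_dataset(regions, SplitPlan(ratio=(6, 2, 2), seed=5))
    assert (tr, va, te) == again
    allitems = sorted(tr + va + te)
    assert allitems == sorted(regions[0] + regions[1])
    assert not (set(tr) & set(va)) and not (set(tr) & set(te)) and not (set(va) & set(te))
    other = split_dataset(regions, SplitPlan(ratio=(6, 2, 2), seed=6))
    assert (len(other[0]), len(other[1]), len(other[2])) == (len(tr), len(va), len(te))


def test_split_size_deviation_below_one_item_per_region():
    tr, va, te = split_dataset([list(range(11))], SplitPlan(ratio=(6, 2, 2), seed=0))
    for got, want in zip((len(tr), len(va), len(te)), (6.6, 2.2, 2.2)):
        assert abs(got - want) < 1.0


def test_split_rejects_bad_input():
    with pytest.raises(ValueError, match="positive"):
        SplitPlan(ratio=(6, 0, 4))
    with pytest.raises(ValueError, match="non-empty"):
        split_dataset([[]], SplitPlan())


def test_mask_png_round_trip(tmp_path):
    mask = (np.random.default_rng(0).random((12, 12)) > 0.5).astype(np.uint8)
    p = tmp_path / "m.png"
    save_mask(mask, p)
    assert np.array_equal(load_mask(p), mask)
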