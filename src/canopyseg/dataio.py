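"""Dataset I/O: polygon annotations, mask rasterization, resizing, splits.

Annotations follow the Labelme JSON layout (``imageHeight``, ``imageWidth``,
``shapes[{label, points}]``).  Rasterization uses the pixel-center /
even-odd dialect: a pixel belongs to a polygon iff its center (x+0.5,
y+0.5) lies inside under the even-odd (crossing-parity) rule; overlapping
plant polygons union.  Splitting shuffles each acquisition region
independently with a recorded seed and cuts at the cumulative ratio with
largest-remainder rounding, then concatenates per-split across regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "PolygonAnnotation",
    "SplitPlan",
    "read_labelme",
    "labelme_to_mask",
    "rasterize_polygon",
    "resize_pair",
    "split_dataset",
    "save_mask",
    "load_mask",
    "AnnotationError",
]

PLANT_LABELS = frozenset({"plant", "lettuce"})


class AnnotationError(ValueError):
    """Raised for malformed polygon annotations."""


@dataclass
class PolygonAnnotation:
    image_size: tuple[int, int]  # (H, W)
    polygons: list[tuple[str, np.ndarray]] = field(default_factory=list)  # (label, (n,2) xy)


@dataclass
class SplitPlan:
    ratio: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    per_region: bool = True

    def __post_init__(self):
        if any(r <= 0 for r in self.ratio):
            raise ValueError(f"split ratio components must be positive, got {self.ratio}")
        s = sum(self.ratio)
        self.ratio = tuple(r / s for r in self.ratio)


def read_labelme(path: str | Path) -> PolygonAnnotation:
    """Parse a Labelme JSON file into a :class:`PolygonAnnotation`."""
    with open(path) as fh:
        doc = json.load(fh)
    size = (int(doc["imageHeight"]), int(doc["imageWidth"]))
    polys = []
    for shape in doc.get("shapes", []):
        pts = np.asarray(shape["points"], dtype=float)
        polys.append((shape["label"], pts))
    return PolygonAnnotation(image_size=size, polygons=polys)


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd fill of one polygon on an (H, W) grid, pixel-center test.

    Crossing-number parity of a horizontal ray from each pixel center
    (x + 0.5, y + 0.5); identical to the even-odd rule.
    """
    H, W = shape
    verts = np.asarray(vertices, dtype=float)
    xc = np.arange(W) + 0.5  # (W,)
    yc = (np.arange(H) + 0.5)[:, None]  # (H, 1)
    inside = np.zeros((H, W), dtype=np.int32)
    n = len(verts)
    for k in range(n):
        x1, y1 = verts[k]
        x2, y2 = verts[(k + 1) % n]
        if y1 == y2:
            continue
        straddles = (y1 <= yc[:, 0]) != (y2 <= yc[:, 0])  # (H,)
        with np.errstate(invalid="ignore"):
            xint = x1 + (yc[:, 0] - y1) * (x2 - x1) / (y2 - y1)  # (H,)
        inside += (straddles[:, None] & (xc[None, :] < xint[:, None])).astype(np.int32)
    return (inside % 2 == 1).astype(np.uint8)


def labelme_to_mask(ann: PolygonAnnotation, plant_labels: frozenset[str] = PLANT_LABELS) -> np.ndarray:
    """Rasterize all plant polygons onto a zero background; overlaps union."""
    H, W = ann.image_size
    mask = np.zeros((H, W), dtype=np.uint8)
    for idx, (label, verts) in enumerate(ann.polygons):
        if len(verts) < 3:
            raise AnnotationError(f"polygon {idx} (label {label!r}) has {len(verts)} vertices; need >= 3")
        if label not in plant_labels:
            continue
        mask |= rasterize_polygon(verts, (H, W))
    return mask


def resize_pair(image: np.ndarray, mask: np.ndarray, size: int = 640) -> tuple[np.ndarray, np.ndarray]:
    """Resize an (H, W, 3) image bilinearly and its mask by nearest neighbour."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape:
        raise ValueError(f"image {image.shape[:2]} and mask {mask.shape} spatial shapes differ")
    if image.shape[:2] == (size, size):
        return image, mask
    img = Image.fromarray(image.astype(np.uint8)).resize((size, size), Image.BILINEAR)
    msk = Image.fromarray(mask.astype(np.uint8)).resize((size, size), Image.NEAREST)
    return np.asarray(img), np.asarray(msk)


def _largest_remainder(n: int, ratio: tuple[float, ...]) -> list[int]:
    exact = [n * r for r in ratio]
    base = [int(np.floor(e)) for e in exact]
    rem = n - sum(base)
    order = np.argsort([b - e for b, e in zip(base, exact)])  # most-negative remainder first
    for i in range(rem):
        base[order[i]] += 1
    return base


def split_dataset(region_sets: list[list], plan: SplitPlan) -> tuple[list, list, list]:
    """Shuffle-and-cut each region at the plan ratio, then merge per split."""
    if not region_sets or any(len(r) == 0 for r in region_sets):
        raise ValueError("every region set must be non-empty")
    rng = np.random.default_rng(plan.seed)
    train: list = []
    val: list = []
    test: list = []
    for region in region_sets:
        items = list(region)
        rng.shuffle(items)
        n_tr, n_va, n_te = _largest_remainder(len(items), plan.ratio)
        train.extend(items[:n_tr])
        val.extend(items[n_tr : n_tr + n_va])
        test.extend(items[n_tr + n_va :])
    return train, val, test


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit single-channel PNG with values {0, 1}."""
    Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L").save(path)


def load_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 0).astype(np.uint8)
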