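"""Canopy-coverage statistics from binary plant/background masks.

Coverage is the pixel-ratio phenotype: the fraction of the imaged viewing
area occupied by plant pixels.  *Group* coverage counts every plant pixel;
*individual* coverage splits the plant area into 8-connected components,
one per (non-occluded) plant.  Plants whose leaves touch merge into one
component — a known limitation in late growth stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "CoverageRecord",
    "group_coverage",
    "threshold_mask",
    "instance_coverage",
    "bin_coverages",
    "coverage_series",
]


@dataclass
class CoverageRecord:
    """Per-image coverage: the group fraction and one fraction per plant region."""

    image_id: str
    group_coverage: float
    instance_coverages: list[float] = field(default_factory=list)
    stage: int | None = None
    variety: str | None = None


def _require_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask must be binary (0 = background, 1 = plant); found values {vals[:10]}")
    return mask


def group_coverage(mask: np.ndarray) -> float:
    """Plant-pixel count over total pixel count, as a fraction in [0, 1]."""
    mask = _require_binary(mask)
    return float(int(mask.sum()) / mask.size)


def threshold_mask(prob: np.ndarray, tau: float, plant_class: int = 1) -> np.ndarray:
    """Label a pixel plant iff its plant-class probability is >= ``tau``.

    ``prob`` is a (num_classes, H, W) per-pixel probability map; at
    tau = 0.5 this reproduces the two-class argmax rule.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"threshold tau must lie strictly in (0, 1), got {tau}")
    prob = np.asarray(prob)
    if prob.ndim != 3:
        raise ValueError(f"probability map must be (num_classes, H, W), got shape {prob.shape}")
    return (prob[plant_class] >= tau).astype(np.uint8)


def instance_coverage(mask: np.ndarray, min_area: int = 1) -> list[float]:
    """Per-plant coverage fractions via 8-connected component labelling.

    Components smaller than ``min_area`` pixels are dropped, so the
    fractions sum to the group coverage exactly only at min_area = 1.
    Sorted descending.
    """
    mask = _require_binary(mask)
    labels = measure.label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())[1:]  # skip background label 0
    areas = areas[areas >= min_area]
    total = mask.size
    return sorted((int(a) / total for a in areas), reverse=True)


def bin_coverages(values: list[float], width: float = 0.01) -> dict[tuple[float, float], int]:
    """Histogram coverage fractions into half-open bins [k*width, (k+1)*width).

    Default width 0.01 gives the 1-percentage-point bins used to grade
    individual growth differences (0-1%, 1-2%, 2-3%, ...).
    """
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {width}")
    hist: dict[tuple[float, float], int] = {}
    for v in values:
        k = int(np.floor(v / width))
        edge = (k * width, (k + 1) * width)
        hist[edge] = hist.get(edge, 0) + 1
    return dict(sorted(hist.items()))


def coverage_series(records: list[CoverageRecord]) -> pd.DataFrame:
    """Mean and sd of group coverage grouped by (variety, stage).

    Stages sort ascending within each variety; a single record in a cell
    yields sd 0.  Input order does not matter.
    """
    rows = [
        {"variety": r.variety, "stage": r.stage, "coverage": r.group_coverage}
        for r in records
        if r.stage is not None and r.variety is not None
    ]
    if not rows:
        return pd.DataFrame(columns=["variety", "stage", "mean_coverage", "sd_coverage", "n"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["variety", "stage"], as_index=False)
        .agg(mean_coverage=("coverage", "mean"), sd_coverage=("coverage", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0), n=("coverage", "size"))
        .sort_values(["variety", "stage"], ignore_index=True)
    )
    return out
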