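"""Procedural canopy-scene generator with exact ground-truth masks.

Emulates the acquisition design behind the package: two growing regions,
five acquisition sessions (growth stages S1-S5) per region, 100 images per
session, three lettuce variety appearance profiles (V1-V3).  Each scene is
a grid of rosette "plants" — overlapping rotated elliptical leaves —
composited over a dark hydroponic-board background with speckle, an
illumination gradient (stronger in region R1, a two-site lighting proxy)
and additive colour noise.  The plant mask is the exact union of the drawn
leaf supports, evaluated analytically at pixel centers; colour noise never
touches it.  Plant radius grows strictly with stage, so expected coverage
rises with stage until inter-plant overlap saturates; late stages overlap
deliberately to exercise the merged-instance limitation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.color import hsv2rgb

from .coverage import CoverageRecord, instance_coverage

__all__ = [
    "VarietyProfile",
    "VARIETIES",
    "SceneSpec",
    "SessionSpec",
    "generate_scene",
    "generate_dataset",
    "default_schedule",
    "tiny_schedule",
]


@dataclass(frozen=True)
class VarietyProfile:
    """Appearance knobs for one cultivar: rosette shape and hue band."""

    leaf_range: tuple[int, int]
    elongation: float
    hue_range: tuple[float, float]
    size_mult: float = 1.0
    leaf_scale_range: tuple[float, float] = (0.55, 0.85)
    offset_frac: float = 0.35


VARIETIES: dict[str, VarietyProfile] = {
    # compact, roundish leaves, mid green
    "V1": VarietyProfile((6, 9), 1.6, (0.26, 0.31), 0.95),
    # frilly, many elongated leaves, yellow-green
    "V2": VarietyProfile((8, 12), 2.2, (0.22, 0.27), 1.0),
    # loose head, few broad leaves, deeper green
    "V3": VarietyProfile((5, 8), 1.3, (0.30, 0.36), 1.05),
    # degenerate single-disc plant used for geometric calibration checks
    "disc": VarietyProfile((1, 1), 1.0, (0.28, 0.30), 1.0, (1.0, 1.0), 0.0),
}

# radius growth per stage relative to the grid cell; strictly increasing
_STAGE_GAIN = 0.35
_BASE_FRAC = 0.16


def stage_radius(stage: int, cell: float, variety: str = "V1") -> float:
    """Base plant radius in pixels for a growth stage (strictly increasing)."""
    if not 1 <= stage <= 5:
        raise ValueError(f"stage must be in 1..5, got {stage}")
    return _BASE_FRAC * cell * (1.0 + _STAGE_GAIN * (stage - 1)) * VARIETIES[variety].size_mult


@dataclass
class SceneSpec:
    """Parameters of one synthetic canopy image."""

    canvas: tuple[int, int] = (640, 640)
    grid: tuple[int, int] = (4, 4)
    jitter_sd: float = 0.03  # positional jitter, fraction of a grid cell
    stage: int = 3
    variety: str = "V1"
    base_radius: float | None = None  # overrides stage_radius() when set
    noise_sd: float = 0.02
    illumination_amp: float = 0.15
    seed: int = 0


@dataclass(frozen=True)
class SessionSpec:
    """One acquisition session: a region visited at one growth stage."""

    region: str
    stage: int
    n_images: int
    varieties: tuple[str, ...] = ("V1", "V2", "V3")
    illumination_amp: float = 0.15


def _ellipse_union(mask: np.ndarray, cx: float, cy: float, a: float, b: float, theta: float) -> None:
    """OR the support of a rotated ellipse (pixel-center test) into ``mask``."""
    H, W = mask.shape
    r = max(a, b)
    y0, y1 = max(0, int(np.floor(cy - r))), min(H, int(np.ceil(cy + r)) + 1)
    x0, x1 = max(0, int(np.floor(cx - r))), min(W, int(np.ceil(cx + r)) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1) + 0.5 - cy
    xx = np.arange(x0, x1) + 0.5 - cx
    dx = xx[None, :]
    dy = yy[:, None]
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    mask[y0:y1, x0:x1] |= (u * u + v * v <= 1.0)


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray, CoverageRecord]:
    """Render one canopy scene.

    Returns the (H, W, 3) uint8 image, the exact (H, W) uint8 plant mask,
    and a :class:`CoverageRecord` holding the ground-truth group and
    per-component coverages.  Deterministic given ``spec.seed``.
    """
    if spec.variety not in VARIETIES:
        raise ValueError(f"unknown variety {spec.variety!r}; known: {sorted(VARIETIES)}")
    H, W = spec.canvas
    rows, cols = spec.grid
    if rows < 1 or cols < 1:
        raise ValueError(f"grid must be at least 1x1, got {spec.grid}")
    cell = min(H / rows, W / cols)
    prof = VARIETIES[spec.variety]
    radius = spec.base_radius if spec.base_radius is not None else stage_radius(spec.stage, cell, spec.variety)
    if radius > min(H, W) / 2:
        raise ValueError(f"plant radius {radius:.1f}px exceeds half the canvas {spec.canvas}; thin the grid")

    rng = np.random.default_rng(spec.seed)
    mask = np.zeros((H, W), dtype=bool)
    leaves: list[tuple[float, float, float, float, float, float]] = []  # cx, cy, a, b, theta, hue
    for gi in range(rows):
        for gj in range(cols):
            py = (gi + 0.5) * H / rows + rng.normal(0.0, spec.jitter_sd * cell)
            px = (gj + 0.5) * W / cols + rng.normal(0.0, spec.jitter_sd * cell)
            n_leaves = int(rng.integers(prof.leaf_range[0], prof.leaf_range[1] + 1))
            base_angle = rng.uniform(0, 2 * np.pi)
            for k in range(n_leaves):
                ang = base_angle + 2 * np.pi * k / n_leaves + rng.normal(0.0, 0.25)
                a = radius * rng.uniform(*prof.leaf_scale_range)
                b = a / prof.elongation
                off = prof.offset_frac * radius
                cx = px + off * np.cos(ang)
                cy = py + off * np.sin(ang)
                hue = rng.uniform(*prof.hue_range)
                leaves.append((cx, cy, a, b, ang, hue))

    # background: dark board, speckle, horizontal illumination ramp
    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = (0.13, 0.12, 0.11)
    img += rng.normal(0.0, 0.015, size=(H, W, 1))
    ramp = spec.illumination_amp * (np.linspace(-0.5, 0.5, W)[None, :, None])
    img += ramp
    # occasional specular glints on the board
    glint = rng.random((H, W)) > 0.999
    img[glint] = 0.85

    # paint leaves back-to-front; the mask is the exact union of supports
    if radius > 0:
        for cx, cy, a, b, theta, hue in leaves:
            sup = np.zeros((H, W), dtype=bool)
            _ellipse_union(sup, cx, cy, a, b, theta)
            mask |= sup
            sat = rng.uniform(0.55, 0.8)
            val = rng.uniform(0.35, 0.7)
            rgb = hsv2rgb(np.array([[[hue, sat, val]]]))[0, 0]
            shade = 1.0 + 0.12 * np.sin(3.0 * theta)  # cheap per-leaf shading cue
            img[sup] = rgb * shade

    img += rng.normal(0.0, spec.noise_sd, size=(H, W, 3))
    img = np.clip(img, 0.0, 1.0)
    image = (img * 255.0 + 0.5).astype(np.uint8)
    mask8 = mask.astype(np.uint8)

    record = CoverageRecord(
        image_id=f"scene_{spec.seed}",
        group_coverage=float(int(mask8.sum()) / mask8.size),
        instance_coverages=instance_coverage(mask8),
        stage=spec.stage,
        variety=spec.variety,
    )
    return image, mask8, record


def default_schedule(n_per_session: int = 100) -> list[SessionSpec]:
    """The full acquisition design: 2 regions x 5 sessions x 100 images."""
    sched = []
    for region, amp in (("R1", 0.20), ("R2", 0.10)):
        for stage in range(1, 6):
            sched.append(SessionSpec(region=region, stage=stage, n_images=n_per_session, illumination_amp=amp))
    return sched


def tiny_schedule(n_per_session: int = 2) -> list[SessionSpec]:
    """A reduced schedule (both regions, all stages, few images) for quick runs."""
    return default_schedule(n_per_session)


def generate_dataset(
    schedule: list[SessionSpec],
    out_dir: str | Path,
    seed: int = 0,
    canvas: tuple[int, int] = (640, 640),
    grid: tuple[int, int] = (4, 4),
) -> Path:
    """Write images, masks and a manifest CSV for a whole schedule.

    Returns the manifest path.  Per-image seeds are spawned from ``seed``
    so any single image can be regenerated independently.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    total = sum(s.n_images for s in schedule)
    children = np.random.SeedSequence(seed).spawn(total)
    rows = []
    idx = 0
    for sess in schedule:
        for i in range(sess.n_images):
            variety = sess.varieties[i % len(sess.varieties)]
            child_seed = int(children[idx].generate_state(1)[0] % (2**31))
            idx += 1
            spec = SceneSpec(
                canvas=canvas,
                grid=grid,
                stage=sess.stage,
                variety=variety,
                illumination_amp=sess.illumination_amp,
                seed=child_seed,
            )
            image, mask, rec = generate_scene(spec)
            image_id = f"{sess.region}_s{sess.stage}_{i:03d}"
            img_path = out / "images" / f"{image_id}.png"
            msk_path = out / "masks" / f"{image_id}.png"
            Image.fromarray(image).save(img_path)
            Image.fromarray(mask, mode="L").save(msk_path)
            rows.append(
                {
                    "image_id": image_id,
                    "region": sess.region,
                    "stage": sess.stage,
                    "variety": variety,
                    "seed": child_seed,
                    "true_coverage": rec.group_coverage,
                    "image_path": str(img_path),
                    "mask_path": str(msk_path),
                }
            )
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return manifest
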