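"""Training and evaluation engine.

Training follows a two-phase schedule: a *freeze* phase in which backbone
parameters are held fixed (only attention, PPM and classifier learn),
followed by an *unfreeze* phase training everything, typically at a lower
learning rate.  The loss is pixel-wise cross-entropy (+ 0.4-weighted
auxiliary cross-entropy when the aux head is enabled).  A SHA-256 hash of
the backbone parameters is recorded every epoch so the freeze contract is
verifiable; checkpoints embed the model spec so inference can rebuild the
network from the weight file alone.
"""

from __future__ import annotations

import csv
import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .metrics import ConfusionMatrix, confusion_matrix, iou_per_class, miou, pixel_accuracy
from .network import ModelSpec, SegModel, assemble_model, load_checkpoint, predict, save_checkpoint
from .nn.tensor import Tensor, cross_entropy

__all__ = ["TrainPlan", "TrainResult", "train", "evaluate", "bench", "load_manifest", "backbone_hash"]

AUX_LOSS_WEIGHT = 0.4


@dataclass
class TrainPlan:
    freeze_epochs: int = 2
    unfreeze_epochs: int = 8
    batch_size: int = 2
    lr_freeze: float = 1e-3
    lr_unfreeze: float = 1e-4
    optimizer: str = "sgd"  # or "adam"
    momentum: float = 0.9
    weight_decay: float = 0.0
    lr_decay: float = 1.0  # per-epoch multiplicative decay within a phase
    image_size: int = 640
    seed: int = 0
    val_interval: int = 1  # validate every k-th epoch (and always the last)
    checkpoint_dir: str = "checkpoints"

    def __post_init__(self):
        if self.freeze_epochs < 0 or self.unfreeze_epochs < 0:
            raise ValueError("epoch counts must be non-negative")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"optimizer must be 'sgd' or 'adam', got {self.optimizer!r}")

    @property
    def total_epochs(self) -> int:
        return self.freeze_epochs + self.unfreeze_epochs


@dataclass
class TrainResult:
    checkpoint: Path
    history: list[dict] = field(default_factory=list)


def load_manifest(path: str | Path) -> list[dict]:
    """Read a dataset manifest CSV into a list of row dicts."""
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def _load_pair(row: dict, size: int) -> tuple[np.ndarray, np.ndarray]:
    img_path, msk_path = Path(row["image_path"]), Path(row["mask_path"])
    for p in (img_path, msk_path):
        if not p.exists():
            raise FileNotFoundError(f"dataset file missing: {p}")
    img = Image.open(img_path).convert("RGB")
    msk = Image.open(msk_path).convert("L")
    if img.size != (size, size):
        img = img.resize((size, size), Image.BILINEAR)
        msk = msk.resize((size, size), Image.NEAREST)
    x = np.asarray(img, dtype=np.float32).transpose(2, 0, 1) / 255.0
    y = (np.asarray(msk) > 0).astype(np.int64)
    return x, y


def backbone_hash(model: SegModel) -> str:
    """SHA-256 over all backbone parameter bytes, in name order."""
    h = hashlib.sha256()
    for name, p in sorted(model.backbone.named_parameters()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


def _make_optimizer(plan: TrainPlan, params, lr: float):
    if plan.optimizer == "adam":
        return nn.Adam(params, lr=lr, weight_decay=plan.weight_decay)
    return nn.SGD(params, lr=lr, momentum=plan.momentum, weight_decay=plan.weight_decay)


def _epoch(model: SegModel, batches, optimizer) -> float:
    losses = []
    for xb, yb in batches:
        optimizer.zero_grad()
        if model.aux is not None:
            logits, aux_logits = model(Tensor(xb), return_aux=True)
            loss = cross_entropy(logits, yb) + AUX_LOSS_WEIGHT * cross_entropy(aux_logits, yb)
        else:
            loss = cross_entropy(model(Tensor(xb)), yb)
        loss.backward()
        optimizer.step()
        losses.append(float(loss.data))
    return float(np.mean(losses))


def train(
    spec: ModelSpec,
    train_manifest: str | Path | list[dict],
    plan: TrainPlan,
    val_manifest: str | Path | list[dict] | None = None,
) -> TrainResult:
    """Run the freeze/unfreeze schedule and save the best (or final) checkpoint."""
    rows = train_manifest if isinstance(train_manifest, list) else load_manifest(train_manifest)
    if not rows:
        raise ValueError("train split is empty")
    val_rows = None
    if val_manifest is not None:
        val_rows = val_manifest if isinstance(val_manifest, list) else load_manifest(val_manifest)

    nn.manual_seed(plan.seed)
    model = assemble_model(spec)
    rng = np.random.default_rng(plan.seed)
    data = [_load_pair(r, plan.image_size) for r in rows]

    ckpt_dir = Path(plan.checkpoint_dir)
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    ckpt_path = ckpt_dir / "model.npz"
    history: list[dict] = []
    best_val = -np.inf

    def run_phase(n_epochs: int, lr: float, frozen: bool, epoch_offset: int):
        nonlocal best_val
        for p in model.backbone.parameters():
            p.requires_grad = not frozen
        optimizer = _make_optimizer(plan, [p for p in model.parameters() if p.requires_grad], lr)
        for e in range(n_epochs):
            optimizer.lr = lr * (plan.lr_decay ** e)
            order = rng.permutation(len(data))
            batches = []
            for i in range(0, len(order), plan.batch_size):
                idx = order[i : i + plan.batch_size]
                batches.append((np.stack([data[j][0] for j in idx]), np.stack([data[j][1] for j in idx])))
            model.train()
            loss = _epoch(model, batches, optimizer)
            entry = {
                "epoch": epoch_offset + e,
                "phase": "freeze" if frozen else "unfreeze",
                "train_loss": loss,
                "backbone_hash": backbone_hash(model),
            }
            if val_rows and (e % plan.val_interval == 0 or e == n_epochs - 1):
                report = evaluate(model, val_rows, image_size=plan.image_size)
                entry["val_miou"] = report["miou"]
                if report["miou"] > best_val:
                    best_val = report["miou"]
                    save_checkpoint(model, ckpt_path)
            history.append(entry)

    run_phase(plan.freeze_epochs, plan.lr_freeze, frozen=True, epoch_offset=0)
    run_phase(plan.unfreeze_epochs, plan.lr_unfreeze, frozen=False, epoch_offset=plan.freeze_epochs)
    for p in model.backbone.parameters():
        p.requires_grad = True

    if not val_rows or not ckpt_path.exists():
        save_checkpoint(model, ckpt_path)
    return TrainResult(checkpoint=ckpt_path, history=history)


def evaluate(
    model_or_checkpoint: SegModel | str | Path,
    manifest: str | Path | list[dict],
    image_size: int = 640,
) -> dict:
    """Accumulate one confusion matrix over a split; report PA, IoU, MIoU."""
    model = model_or_checkpoint if isinstance(model_or_checkpoint, SegModel) else load_checkpoint(model_or_checkpoint)
    rows = manifest if isinstance(manifest, list) else load_manifest(manifest)
    C = model.spec.num_classes
    cm = ConfusionMatrix(np.zeros((C, C), dtype=np.int64))
    n_images = 0
    for row in rows:
        x, y = _load_pair(row, image_size)
        if int(y.max()) >= C:
            raise ValueError(f"mask {row['mask_path']} has labels >= num_classes={C}")
        pred = predict(model, x)
        cm = cm + confusion_matrix(y, pred.mask, C)
        n_images += 1
    iou = iou_per_class(cm)
    return {
        "pa": pixel_accuracy(cm),
        "iou_background": float(iou[0]),
        "iou_plant": float(iou[1]) if C > 1 else float("nan"),
        "miou": miou(cm),
        "n_images": n_images,
        "n_pixels": cm.total,
    }


def bench(model_or_checkpoint: SegModel | str | Path, n_images: int = 5, image_size: int = 64) -> dict:
    """Parameter count, checkpoint file size, and CPU latency/FPS (informative)."""
    if isinstance(model_or_checkpoint, SegModel):
        model = model_or_checkpoint
        file_size = None
    else:
        model = load_checkpoint(model_or_checkpoint)
        file_size = Path(model_or_checkpoint).stat().st_size
    model.eval()
    rng = np.random.default_rng(0)
    x = rng.random((3, image_size, image_size), dtype=np.float32)
    predict(model, x)  # warm-up
    t0 = time.perf_counter()
    for _ in range(n_images):
        predict(model, x)
    elapsed = time.perf_counter() - t0
    return {
        "param_count": nn.parameter_count(model),
        "file_size": file_size,
        "mean_latency": elapsed / n_images,
        "fps": n_images / elapsed,
    }
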