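"""Shared fixtures: tiny synthetic datasets and one session-scoped overfit run."""

import numpy as np
import pytest
from PIL import Image

from canopyseg.attention import AttentionSpec
from canopyseg.backbones import BackboneSpec
from canopyseg.harness import TrainPlan, evaluate, train
from canopyseg.network import ModelSpec
from canopyseg.synthdata import SceneSpec, generate_scene


def write_pairs(scenes, out_dir):
    """Render scenes to PNG pairs; return manifest rows."""
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(scenes):
        image, mask, rec = generate_scene(spec)
        img_path = out_dir / "images" / f"img_{i}.png"
        msk_path = out_dir / "masks" / f"msk_{i}.png"
        Image.fromarray(image).save(img_path)
        Image.fromarray(mask, mode="L").save(msk_path)
        rows.append(
            {
                "image_id": f"img_{i}",
                "region": "R1",
                "stage": str(spec.stage),
                "variety": spec.variety,
                "seed": str(spec.seed),
                "true_coverage": str(rec.group_coverage),
                "image_path": str(img_path),
                "mask_path": str(msk_path),
            }
        )
    return rows


@pytest.fixture(scope="session")
def disc_scene_rows(tmp_path_factory):
    """Four 64x64 disc-profile scenes: a cleanly separable two-class toy."""
    out = tmp_path_factory.mktemp("disc_scenes")
    scenes = [
        SceneSpec(canvas=(64, 64), grid=(1, 1), stage=4 + (i % 2), variety="disc", seed=100 + i)
        for i in range(4)
    ]
    return write_pairs(scenes, out)


@pytest.fixture(scope="session")
def overfit_run(disc_scene_rows, tmp_path_factory):
    """Train CAS-PSPNet (MobileNetV3 trunk, stride 8) to overfit the toy set.

    Session-scoped: the freeze-contract, loss-decrease and accuracy checks
    all read this single run.
    """
    ckpt_dir = tmp_path_factory.mktemp("overfit_ckpt")
    spec = ModelSpec(
        backbone=BackboneSpec("mobilenetv3", output_stride=8),
        attention=AttentionSpec(kind="cas"),
    )
    plan = TrainPlan(
        freeze_epochs=2,
        unfreeze_epochs=108,
        batch_size=4,
        lr_freeze=5e-3,
        lr_unfreeze=5e-3,
        lr_decay=0.985,
        optimizer="adam",
        image_size=64,
        seed=0,
        val_interval=5,
        checkpoint_dir=str(ckpt_dir),
    )
    result = train(spec, disc_scene_rows, plan, val_manifest=disc_scene_rows)
    report = evaluate(result.checkpoint, disc_scene_rows, image_size=64)
    return {"result": result, "report": report, "plan": plan, "rows": disc_scene_rows}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
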