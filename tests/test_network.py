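"""Model assembly: pyramid pooling contract, softmax simplex, checkpoints."""

import numpy as np
import pytest

from canopyseg import nn
from canopyseg.attention import CAS, AttentionSpec
from canopyseg.backbones import BackboneSpec
from canopyseg.network import (
    ModelSpec,
    PyramidPooling,
    assemble_model,
    load_checkpoint,
    ppm_forward,
    predict,
    save_checkpoint,
)
from canopyseg.nn.tensor import Tensor


def small_spec(attention="none", backbone="mobilenetv3", stride=8, scales=(1, 2, 3, 6)):
    return ModelSpec(
        backbone=BackboneSpec(backbone, stride),
        attention=AttentionSpec(kind=attention),
        ppm_scales=scales,
    )


class TestPyramidPooling:
    @pytest.mark.parametrize("size", [6, 8, 13])
    def test_concat_doubles_channels_and_keeps_spatial_size(self, rng, size):
        C = 16
        ppm = PyramidPooling(C, (1, 2, 3, 6))
        f = rng.normal(size=(C, size, size)).astype(np.float32)
        fused, cat = ppm_forward(f, module=ppm, return_concat=True)
        assert cat.shape == (2 * C, size, size)
        assert fused.shape == (C // 4, size, size)

    def test_constant_input_pools_to_constant_branches(self, rng):
        C = 8
        ppm = PyramidPooling(C, (1, 2))
        f = np.broadcast_to(rng.normal(size=(C, 1, 1)), (C, 6, 6)).astype(np.float32)
        # adaptive average pooling of a constant map is that constant
        pooled = nn.functional.adaptive_avg_pool2d(Tensor(f[None]), 2)
        assert np.allclose(pooled.data, f[:, :2, :2], atol=1e-6)

    def test_single_scale_degenerate(self, rng):
        f = rng.normal(size=(8, 5, 5)).astype(np.float32)
        out = ppm_forward(f, scales=(1,), module=PyramidPooling(8, (1,)))
        assert out.shape == (2, 5, 5)

    def test_input_smaller_than_scale_rejected(self, rng):
        ppm = PyramidPooling(8, (1, 2, 3, 6))
        with pytest.raises(ValueError, match="6"):
            ppm_forward(rng.normal(size=(8, 4, 4)).astype(np.float32), module=ppm)

    def test_branch_count_tracks_scales(self):
        assert len(PyramidPooling(16, (1, 2, 3, 6)).branches) == 4
        assert len(PyramidPooling(16, (1, 3)).branches) == 2


class TestModelSpec:
    def test_rejects_bad_scales_and_classes(self):
        with pytest.raises(ValueError, match="increasing"):
            ModelSpec(ppm_scales=(1, 3, 2))
        with pytest.raises(ValueError, match="num_classes"):
            ModelSpec(num_classes=1)

    def test_round_trips_through_dict(self):
        spec = small_spec("cas")
        again = ModelSpec.from_dict(spec.to_dict())
        assert again == spec


@pytest.fixture(scope="module")
def model():
    nn.manual_seed(0)
    return assemble_model(small_spec("cas"))


class TestSegModel:
    def test_end_to_end_shapes(self, model, rng):
        x = rng.random((3, 64, 64)).astype(np.float32)
        pred = predict(model, x)
        assert pred.prob.shape == (2, 64, 64)
        assert pred.mask.shape == (64, 64)
        assert set(np.unique(pred.mask)) <= {0, 1}

    def test_softmax_simplex(self, model, rng):
        pred = predict(model, rng.random((3, 64, 64)).astype(np.float32))
        assert np.allclose(pred.prob.sum(axis=0), 1.0, atol=1e-5)
        assert (pred.prob >= 0).all()

    def test_eval_determinism_and_batch_consistency(self, model, rng):
        x = rng.random((3, 64, 64)).astype(np.float32)
        p1, p2 = predict(model, x), predict(model, x)
        assert np.array_equal(p1.prob, p2.prob)
        model.eval()
        batch = model(Tensor(np.stack([x, x])))
        assert np.allclose(batch.data[0], batch.data[1], atol=1e-6)

    def test_zeroed_classifier_gives_uniform_probabilities(self, rng):
        nn.manual_seed(1)
        m = assemble_model(small_spec("none"))
        m.classifier.weight.data = np.zeros_like(m.classifier.weight.data)
        m.classifier.bias.data = np.zeros_like(m.classifier.bias.data)
        pred = predict(m, rng.random((3, 64, 64)).astype(np.float32))
        assert np.allclose(pred.prob, 0.5, atol=1e-6)

    def test_wrong_channel_count_rejected(self, model):
        with pytest.raises(ValueError, match="3, H, W"):
            predict(model, np.zeros((1, 64, 64), dtype=np.float32))

    def test_attention_parameter_difference_is_cas_module(self):
        nn.manual_seed(0)
        with_cas = nn.parameter_count(assemble_model(small_spec("cas")))
        without = nn.parameter_count(assemble_model(small_spec("none")))
        cas_alone = nn.parameter_count(CAS(960, AttentionSpec(kind="cas")))
        assert with_cas - without == cas_alone

    def test_lightweight_variant_contract(self, rng):
        nn.manual_seed(2)
        m = assemble_model(small_spec("none", "mobilenetv3", 8))
        pred = predict(m, rng.random((3, 64, 64)).astype(np.float32))
        assert pred.prob.shape == (2, 64, 64)

    def test_aux_head_training_output(self, rng):
        nn.manual_seed(3)
        spec = small_spec("none")
        spec.aux_head = True
        m = assemble_model(spec)
        logits, aux = m(Tensor(rng.random((1, 3, 64, 64)).astype(np.float32)), return_aux=True)
        assert logits.shape == (1, 2, 64, 64) and aux.shape == (1, 2, 64, 64)


def test_checkpoint_round_trip_bit_identical(tmp_path, rng):
    nn.manual_seed(4)
    m = assemble_model(small_spec("eca"))
    x = rng.random((3, 64, 64)).astype(np.float32)
    before = predict(m, x)
    path = save_checkpoint(m, tmp_path / "m.npz")
    m2 = load_checkpoint(path)
    assert m2.spec == m.spec
    after = predict(m2, x)
    assert np.array_equal(before.prob, after.prob)
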