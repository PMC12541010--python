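"""Network architecture: attention analytics, variants, forward contracts."""

import numpy as np
import pytest

from acunet.nn import (ACUNet, AttentionGate, ChannelAttention, Conv2d,
                       ConvBlock, DualAttention, ModelConfig,
                       SpatialAttention, Tensor, build_model,
                       count_parameters)

RNG = np.random.default_rng(7)


def zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


class TestSpatialAttention:
    def test_zero_weights_give_half_map(self):
        att = SpatialAttention(7, RNG)
        zero_params(att)
        x = Tensor(RNG.standard_normal((2, 4, 8, 8)))
        out, a = att(x)
        np.testing.assert_allclose(a.data, 0.5)
        np.testing.assert_allclose(out.data, 0.5 * x.data)

    def test_map_bounded_in_unit_interval(self):
        for _ in range(10):
            att = SpatialAttention(3, RNG)
            _, a = att(Tensor(RNG.standard_normal((1, 3, 6, 6)) * 5))
            assert ((a.data > 0) & (a.data < 1)).all()

    def test_bright_location_attracts_attention(self):
        # positive 1x1 kernel on channel-pooled maps peaks where x is largest
        att = SpatialAttention(1, RNG)
        att.conv.weight.data[...] = 1.0
        att.conv.bias.data[...] = 0.0
        x = np.zeros((1, 4, 4, 4))
        x[:, :, 2, 2] = 10.0
        _, a = att(Tensor(x))
        iy, ix = np.unravel_index(a.data[0, 0].argmax(), (4, 4))
        assert (iy, ix) == (2, 2)


class TestChannelAttention:
    def test_zero_mlp_gives_half_vector(self):
        att = ChannelAttention(8, 4, RNG)
        zero_params(att)
        x = Tensor(RNG.standard_normal((3, 8, 5, 5)))
        out, a = att(x)
        np.testing.assert_allclose(a.data, 0.5)
        np.testing.assert_allclose(out.data, 0.5 * x.data)

    def test_gap_of_constant_channel_is_exact(self):
        x = np.zeros((1, 2, 4, 4))
        x[0, 0] = 3.25
        x[0, 1] = -1.5
        gap = Tensor(x).mean(axis=(2, 3))
        np.testing.assert_array_equal(gap.data, [[3.25, -1.5]])

    def test_vector_bounded(self):
        att = ChannelAttention(16, 8, RNG)
        _, a = att(Tensor(RNG.standard_normal((2, 16, 4, 4)) * 3))
        assert ((a.data > 0) & (a.data < 1)).all()


class TestDualAttention:
    def test_zero_branches_identity_fusion_halves_input(self):
        att = DualAttention(4, 2, 3, RNG)
        zero_params(att.spatial)
        zero_params(att.channel)
        att.fuse.weight.data[...] = np.eye(4)[:, :, None, None]
        att.fuse.bias.data[...] = 0.0
        x = Tensor(RNG.standard_normal((2, 4, 6, 6)))
        np.testing.assert_allclose(att(x).data, 0.5 * x.data, atol=1e-12)

    def test_zero_input_maps_to_zero_without_biases(self):
        att = DualAttention(4, 2, 3, RNG)
        att.fuse.bias.data[...] = 0.0
        out = att(Tensor(np.zeros((1, 4, 4, 4))))
        np.testing.assert_allclose(out.data, 0.0)

    def test_shape_preserved(self):
        att = DualAttention(6, 3, 5, RNG)
        x = Tensor(RNG.standard_normal((2, 6, 10, 12)))
        assert att(x).data.shape == (2, 6, 10, 12)


class TestAttentionGate:
    def test_concat_sigmoid_zero_weights_halve_encoder(self):
        gate = AttentionGate(4, 4, "concat_sigmoid", RNG)
        zero_params(gate)
        enc = Tensor(RNG.standard_normal((1, 4, 6, 6)))
        dec = Tensor(RNG.standard_normal((1, 4, 6, 6)))
        np.testing.assert_allclose(gate(enc, dec).data, 0.5 * enc.data)

    def test_qkv_zero_weights_give_uniform_rows(self):
        gate = AttentionGate(3, 3, "qkv_softmax", RNG)
        zero_params(gate)
        enc = Tensor(RNG.standard_normal((1, 3, 4, 4)))
        dec = Tensor(RNG.standard_normal((1, 3, 4, 4)))
        alpha = gate.coefficients(enc, dec)
        np.testing.assert_allclose(alpha.data, 1.0 / 16)

    def test_qkv_two_position_toy_matches_hand_softmax(self):
        gate = AttentionGate(1, 1, "qkv_softmax", RNG)
        gate.w_q.weight.data[...] = 1.0      # Q = dec values, d = 1
        gate.w_k.weight.data[...] = 1.0      # K = enc values
        enc = Tensor(np.array([2.0, -1.0]).reshape(1, 1, 1, 2))
        dec = Tensor(np.array([0.5, 0.5]).reshape(1, 1, 1, 2))
        alpha = gate.coefficients(enc, dec).data[0]
        scores = np.array([0.5 * 2.0, 0.5 * -1.0])
        expected = np.exp(scores) / np.exp(scores).sum()
        np.testing.assert_allclose(alpha[0], expected, atol=1e-12)
        np.testing.assert_allclose(alpha[1], expected, atol=1e-12)

    def test_qkv_rows_sum_to_one(self):
        for _ in range(5):
            gate = AttentionGate(2, 2, "qkv_softmax", RNG)
            enc = Tensor(RNG.standard_normal((2, 2, 3, 3)))
            dec = Tensor(RNG.standard_normal((2, 2, 3, 3)))
            alpha = gate.coefficients(enc, dec)
            np.testing.assert_allclose(alpha.data.sum(axis=2), 1.0, atol=1e-6)

    def test_decoder_resized_when_coarser(self):
        gate = AttentionGate(4, 8, "concat_sigmoid", RNG)
        enc = Tensor(RNG.standard_normal((1, 4, 8, 8)))
        dec = Tensor(RNG.standard_normal((1, 8, 4, 4)))
        assert gate(enc, dec).data.shape == (1, 4, 8, 8)


class TestConvBlock:
    def test_zero_weights_zero_output(self):
        block = ConvBlock(3, 4, RNG)
        zero_params(block)
        out = block(Tensor(RNG.standard_normal((1, 3, 5, 5))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_relu_output_nonnegative(self):
        block = ConvBlock(3, 4, RNG)
        out = block(Tensor(RNG.standard_normal((2, 3, 6, 6))))
        assert (out.data >= 0).all()


class TestBuildModel:
    def test_seeded_builds_are_identical(self):
        cfg = ModelConfig(seed=5)
        a, b = build_model(cfg), build_model(cfg)
        for (na, pa), (nb, pb) in zip(a.named_parameters(),
                                      b.named_parameters()):
            assert na == nb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_baseline_has_no_attention_parameters(self):
        model = build_model(ModelConfig(variant="baseline"))
        names = [n for n, _ in model.named_parameters()]
        assert not any("att" in n or "gate" in n for n in names)

    def test_variant_parameter_nesting(self):
        counts = {v: count_parameters(build_model(ModelConfig(variant=v)))
                  for v in ("baseline", "channel_only", "spatial_only",
                            "decoder_only", "full")}
        assert counts["baseline"] < counts["channel_only"] < counts["full"]
        assert counts["baseline"] < counts["spatial_only"] < counts["full"]
        assert counts["baseline"] < counts["decoder_only"] < counts["full"]
        base_names = {n for n, _ in
                      build_model(ModelConfig(variant="baseline"))
                      .named_parameters()}
        for v in ("channel_only", "spatial_only", "decoder_only", "full"):
            names = {n for n, _ in
                     build_model(ModelConfig(variant=v)).named_parameters()}
            assert base_names <= names

    def test_single_1x1_conv_parameter_count(self):
        conv = Conv2d(1, 1, 1, RNG)
        assert sum(p.data.size for p in conv.parameters()) == 2

    @pytest.mark.parametrize("kwargs", [
        {"variant": "bogus"}, {"gate_mode": "bogus"}, {"depth": 1},
        {"base_width": 0}, {"spatial_kernel": 4},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)

    def test_config_roundtrip_and_unknown_key(self):
        cfg = ModelConfig(depth=4, variant="spatial_only")
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg
        with pytest.raises(ValueError, match="unknown"):
            ModelConfig.from_dict({"depht": 3})


@pytest.fixture(scope="module")
def model():
    return build_model(ModelConfig(depth=3, base_width=4, seed=1))


class TestForward:
    def test_probabilities_normalised(self, model):
        probs = model.forward(RNG.standard_normal((2, 4, 16, 16)))
        assert probs.min() >= 0 and probs.max() <= 1
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_output_shape_matches_input(self, model):
        probs = model.forward(RNG.standard_normal((1, 4, 64, 64)))
        assert probs.shape == (1, 4, 64, 64)

    def test_non_divisible_shapes_padded_and_cropped(self, model):
        probs = model.forward(RNG.standard_normal((4, 30, 30)))
        assert probs.shape == (4, 30, 30)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-6)

    def test_inference_deterministic(self, model):
        x = RNG.standard_normal((1, 4, 16, 16))
        np.testing.assert_array_equal(model.forward(x), model.forward(x))

    def test_channel_mismatch_rejected(self, model):
        with pytest.raises(ValueError):
            model.forward(RNG.standard_normal((1, 3, 16, 16)))
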