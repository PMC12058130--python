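import numpy as np
import pytest
from scipy.special import expit

from kanbind import nn
from kanbind.model import (BindingSiteNetwork, ConvBlockSpec, ConvLayerSpec,
                           ModelConfig, ABLATION_VARIANT_NAMES, build_model,
                           default_conv_block, load_checkpoint,
                           parameter_count, save_checkpoint,
                           ablation_variant_configs, trace_conv_shapes)
from kanbind.nn.tensor import Tensor


def reference_lstm(x, w_x, w_h, b, peep):
    """Step-by-step gate recursion coded directly from the equations:
    i/f gates see the previous cell state, the o gate the current one,
    h_t = o_t * tanh(c_t).  Independent of the package's fused kernel."""
    T, d = x.shape
    H = w_h.shape[0]
    h = np.zeros(H)
    c = np.zeros(H)
    p_i, p_f, p_o = peep
    out = []
    for t in range(T):
        a = x[t] @ w_x + h @ w_h + b
        a_i, a_f, a_g, a_o = np.split(a, 4)
        i = expit(a_i + p_i * c)
        f = expit(a_f + p_f * c)
        g = np.tanh(a_g)
        c = f * c + i * g
        o = expit(a_o + p_o * c)
        h = o * np.tanh(c)
        out.append(h.copy())
    return np.array(out)


class TestConvShapes:
    def test_valid_conv_length_law(self):
        spec = ConvBlockSpec("b", (ConvLayerSpec(100, 8, 9, pool=1),))
        assert trace_conv_shapes(spec, 198)[0]["conv"] == 190

    def test_kernel_one_is_pointwise(self):
        spec = ConvBlockSpec("b", (ConvLayerSpec(100, 8, 1, pool=1),))
        assert trace_conv_shapes(spec, 198)[0]["conv"] == 198

    def test_too_short_input_names_layer(self):
        spec = default_conv_block(1, 100)
        with pytest.raises(ValueError, match="ConvBlock1 layer 0"):
            trace_conv_shapes(spec, 5)

    def test_default_blocks_match_published_structure(self):
        b1, b2, b3 = (default_conv_block(i, 100) for i in (1, 2, 3))
        assert [(l.out_channels, l.kernel) for l in b1.layers] == [
            (160, 9), (160, 1), (160, 5), (256, 8)]
        assert [(l.out_channels, l.kernel) for l in b2.layers] == [(128, 11), (256, 9)]
        assert [(l.out_channels, l.kernel) for l in b3.layers] == [(180, 1), (256, 8)]

    def test_channel_multiplier_scales_channels(self):
        b2 = default_conv_block(2, 100, channel_multiplier=2)
        assert [l.out_channels for l in b2.layers] == [256, 512]

    def test_symbolic_trace_matches_runtime(self, tiny_config):
        """Lengths predicted by the shape algebra equal observed shapes."""
        model = build_model(tiny_config, seed=0)
        T = tiny_config.tokens_per_sequence
        x = Tensor(np.zeros((2, T, 100), dtype=np.float32))
        for block, spec in zip(model.blocks, tiny_config.block_specs()):
            out = block(x)
            trace = trace_conv_shapes(spec, T)
            assert out.shape == (2, trace[-1]["pool"], trace[-1]["channels"])


class TestConvBlockForward:
    def test_zero_input_zero_biases_propagates_zero(self, rng):
        conv = nn.Conv1d(4, 6, 3, rng, dtype=np.float64)
        conv.bias.data[:] = 0
        out = nn.maxpool1d(nn.relu(conv(Tensor(np.zeros((2, 10, 4))))), 2)
        assert np.array_equal(out.data, np.zeros_like(out.data))

    def test_multiscale_concatenation_order_and_length(self, rng):
        """Per-block flattened vectors concatenate in block order."""
        cfg = ModelConfig(conv_blocks=(1, 2, 3), use_bilstm=False,
                          residual=False, sequence_length=200)
        model = build_model(cfg, seed=0)
        T = cfg.tokens_per_sequence
        x = Tensor(np.random.default_rng(0).normal(
            0, 1, (1, T, 100)).astype(np.float32))
        feats = [model._flatten(b(x)).data for b in model.blocks]
        joined = np.concatenate(feats, axis=1)
        assert joined.shape[1] == model.cnn_dim
        # permuting block order permutes the segments
        perm = np.concatenate([feats[2], feats[0], feats[1]], axis=1)
        assert set(map(float, perm[0])) == set(map(float, joined[0]))


class TestBiLSTM:
    def test_summary_dimensions(self, rng):
        x = Tensor(rng.normal(0, 1, (3, 7, 5)).astype(np.float32))
        concat = nn.BiLSTM(5, 128, np.random.default_rng(0), combine="concat")
        assert concat(x).shape == (3, 256)
        summed = nn.BiLSTM(5, 128, np.random.default_rng(0), combine="sum")
        assert summed(x).shape == (3, 128)

    def test_zero_input_zero_params_zero_summary(self):
        bl = nn.BiLSTM(4, 6, np.random.default_rng(0), dtype=np.float64)
        for p in bl.parameters():
            p.data[:] = 0
        out = bl(Tensor(np.zeros((2, 5, 4))))
        assert np.array_equal(out.data, np.zeros((2, 12)))

    def test_fused_kernel_matches_reference_recursion(self, rng):
        w_x = rng.normal(0, 0.5, (3, 16))
        w_h = rng.normal(0, 0.5, (4, 16))
        b = rng.normal(0, 0.2, 16)
        peep = rng.normal(0, 0.3, (3, 4))
        x = rng.normal(0, 1, (2, 5, 3))
        got = nn.lstm(Tensor(x), Tensor(w_x), Tensor(w_h), Tensor(b),
                      Tensor(peep)).data
        for n in range(2):
            want = reference_lstm(x[n], w_x, w_h, b, peep)
            assert np.abs(got[n] - want).max() < 1e-12

    def test_reversed_input_swaps_direction_summaries(self, rng):
        """Feeding the reversed sequence exchanges what the forward and
        backward passes compute (checked against the reference recursion)."""
        bl = nn.BiLSTM(3, 4, np.random.default_rng(1), dtype=np.float64)
        x = rng.normal(0, 1, (1, 5, 3))
        out = bl(Tensor(x)).data[0]
        fwd = reference_lstm(x[0], bl.w_x_f.data, bl.w_h_f.data, bl.b_f.data,
                             bl.peep_f.data)[-1]
        bwd = reference_lstm(x[0, ::-1], bl.w_x_b.data, bl.w_h_b.data,
                             bl.b_b.data, bl.peep_b.data)[-1]
        assert np.allclose(out, np.concatenate([fwd, bwd]), atol=1e-12)
        out_rev = bl(Tensor(x[:, ::-1].copy())).data[0]
        # forward summary of the reversed input = backward summary run on
        # the forward parameters, i.e. the roles swap
        fwd_rev = reference_lstm(x[0, ::-1], bl.w_x_f.data, bl.w_h_f.data,
                                 bl.b_f.data, bl.peep_f.data)[-1]
        bwd_rev = reference_lstm(x[0], bl.w_x_b.data, bl.w_h_b.data,
                                 bl.b_b.data, bl.peep_b.data)[-1]
        assert np.allclose(out_rev, np.concatenate([fwd_rev, bwd_rev]),
                           atol=1e-12)


class TestFusionAndHead:
    def test_residual_zero_lstm_projection_is_additive_identity(self, tiny_config):
        """With the LSTM projection zeroed, the fused vector reduces to the
        normalized CNN projection: the LSTM branch becomes irrelevant."""
        model = build_model(tiny_config, seed=0)
        model.eval()
        idx = np.random.default_rng(0).integers(0, 64, (2, tiny_config.tokens_per_sequence))
        model.proj_lstm.weight.data[:] = 0
        model.proj_lstm.bias.data[:] = 0
        before = model.forward(idx).data
        for p in model.bilstm.parameters():  # scrambling the dead branch
            p.data[:] = np.random.default_rng(9).normal(0, 1, p.data.shape)
        after = model.forward(idx).data
        assert np.array_equal(before, after)

    def test_residual_on_off_same_fused_width(self, tiny_config):
        from dataclasses import replace
        on = build_model(tiny_config, seed=0)
        off = build_model(replace(tiny_config, residual=False), seed=0)
        idx = np.zeros((1, tiny_config.tokens_per_sequence), dtype=np.int64)
        assert on.forward(idx).shape == off.forward(idx).shape

    def test_dropout_zero_train_eval_identical(self, tiny_config):
        model = build_model(tiny_config, seed=0)  # dropout_rate=0.0
        idx = np.random.default_rng(1).integers(0, 64, (3, tiny_config.tokens_per_sequence))
        model.train()
        a = model.forward(idx).data
        model.eval()
        b = model.forward(idx).data
        assert np.array_equal(a, b)

    def test_null_propagation_gives_half_probability(self, tiny_config):
        """Zero input through a zero final head layer scores exactly 0.5."""
        model = build_model(tiny_config, seed=3)
        last = model.head.layers[-1]
        last.coef.data[:] = 0
        last.base_weight.data[:] = 0
        unk = 64  # the all-zero unknown embedding row
        p = model.predict_proba(np.full((2, tiny_config.tokens_per_sequence),
                                        unk, dtype=np.int64))
        assert np.array_equal(p, [0.5, 0.5])


class TestBuildAndVariants:
    def test_same_seed_same_build_and_forward(self, tiny_config):
        a = build_model(tiny_config, seed=11)
        b = build_model(tiny_config, seed=11)
        for (ka, pa), (kb, pb) in zip(sorted(a.named_parameters()),
                                      sorted(b.named_parameters())):
            assert ka == kb and np.array_equal(pa.data, pb.data)
        idx = np.random.default_rng(0).integers(0, 64, (2, tiny_config.tokens_per_sequence))
        a.eval(), b.eval()
        assert np.array_equal(a.forward(idx).data, b.forward(idx).data)

    def test_all_ablation_variants_constructible(self):
        """Every named variant builds from config alone — no code forks."""
        variants = ablation_variant_configs()
        assert set(variants) == set(ABLATION_VARIANT_NAMES)
        for name, cfg in variants.items():
            model = build_model(cfg, seed=0)
            assert parameter_count(model) > 0, name

    def test_variant_flags(self):
        v = ablation_variant_configs()
        assert v["C-KAN(dna2vec)(ConvBlock2)"].conv_blocks == (2,)
        assert not v["C-KAN(dna2vec)(ConvBlock2)"].use_bilstm
        assert v["C-KAN(dna2vec)(ConvBlock2)-kernel*2"].channel_multiplier == 2
        assert v["C-KAN(Non-dna2vec)C(ConvBlock1/2/3)"].embedding_mode == "trainable"
        assert not v["CB-KAN(dna2vec)C(ConvBlock1/2/3)(Non-Residual)"].residual
        assert v["CBR-MLP(dna2vec)C(ConvBlock1/2/3)(Residual)"].head == "mlp"

    def test_head_ablation_uses_mlp(self, tiny_config):
        from dataclasses import replace
        model = build_model(replace(tiny_config, head="mlp"), seed=0)
        idx = np.zeros((1, tiny_config.tokens_per_sequence), dtype=np.int64)
        assert model.forward(idx).shape == (1,)


class TestParameterCount:
    def test_kan_head_closed_form(self):
        """Spline params (32 D + 32)(G+p) plus base weights 32 D + 32."""
        from kanbind.kan import KAN, SplineGrid
        D = 16
        head = KAN([D, 32, 1], np.random.default_rng(0),
                   grid=SplineGrid(intervals=5, degree=3))
        expected = (32 * D + 1 * 32) * (5 + 3) + (32 * D + 32)
        assert head.num_parameters() == expected

    def test_channel_multiplier_increases_count(self):
        base = build_model(ModelConfig(conv_blocks=(2,), use_bilstm=False,
                                       residual=False), seed=0)
        wide = build_model(ModelConfig(conv_blocks=(2,), use_bilstm=False,
                                       residual=False, channel_multiplier=2),
                           seed=0)
        assert parameter_count(wide) > parameter_count(base)

    def test_frozen_embedding_contributes_nothing(self, tiny_config):
        from dataclasses import replace
        frozen = build_model(tiny_config, seed=0)
        trainable = build_model(replace(tiny_config, embedding_mode="trainable"),
                                seed=0)
        assert (parameter_count(trainable) - parameter_count(frozen)
                == 65 * 100)  # 64 k-mers + unknown row, dim 100


class TestCheckpoint:
    def test_round_trip_reproduces_outputs(self, tiny_config, tmp_path):
        model = build_model(tiny_config, seed=5)
        model.eval()
        idx = np.random.default_rng(2).integers(0, 64, (3, tiny_config.tokens_per_sequence))
        want = model.predict_proba(idx)
        save_checkpoint(model, tmp_path / "ck.npz", extra={"seed": 5})
        back, extra = load_checkpoint(tmp_path / "ck.npz")
        assert extra == {"seed": 5}
        assert np.array_equal(back.predict_proba(idx), want)
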