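"""Architecture contracts: dense connectivity, transitions, batch norm,
channel/spatial attention, classifier head, and gradient correctness."""

import math

import numpy as np
import pytest

from enhancernet import NetworkConfig, build_model, channel_trace
from enhancernet import _autodiff as ad
from enhancernet.network import (
    AttentionStage,
    BatchNorm2d,
    ChannelAttention,
    DenseBlock,
    SpatialAttention,
    Transition,
)

RNG = np.random.default_rng(0)


def _cfg(**kw):
    base = dict(dtype="float64", dropout_rate=0.0, seed=0)
    base.update(kw)
    return NetworkConfig(**base)


def _zero(module):
    for p in module.params():
        p.data[...] = 0.0
    return module


class TestDenseBlock:
    @pytest.mark.parametrize(
        "c_in,L,k,expected",
        [(1, 3, 12, 37), (1, 1, 1, 2), (18, 3, 12, 54)],
    )
    def test_output_channels_are_cin_plus_Lk(self, c_in, L, k, expected):
        cfg = _cfg()
        block = DenseBlock(c_in, L, k, cfg, np.random.default_rng(0))
        assert block.c_out == expected
        x = ad.Tensor(RNG.normal(size=(2, c_in, 4, 10)))
        out = block(x, train=True)
        assert out.data.shape == (2, expected, 4, 10)

    def test_layer_inputs_concatenate_all_predecessors(self):
        cfg = _cfg()
        block = DenseBlock(1, 3, 12, cfg, np.random.default_rng(0))
        # layer l sees c_in + (l-1)*k channels
        assert [l.conv.w.shape[1] for l in block.layers] == [1, 13, 25]

    def test_dense_layer_spatial_size_preserved_and_k_channels(self):
        cfg = _cfg()
        block = DenseBlock(5, 1, 7, cfg, np.random.default_rng(0))
        x = ad.Tensor(RNG.normal(size=(3, 5, 7, 200)))
        y = block.layers[0](x, train=True)
        assert y.data.shape == (3, 7, 7, 200)

    def test_zero_conv_weights_give_zero_output(self):
        cfg = _cfg()
        block = DenseBlock(2, 1, 3, cfg, np.random.default_rng(0))
        layer = block.layers[0]
        layer.conv.w.data[...] = 0.0
        layer.conv.b.data[...] = 0.0
        x = ad.Tensor(RNG.normal(size=(2, 2, 3, 8)))
        assert np.all(layer(x, train=True).data == 0.0)


class TestTransition:
    def test_compression_and_ceil_pooling(self):
        cfg = _cfg()
        tr = Transition(37, 0.5, cfg, np.random.default_rng(0))
        assert tr.c_out == 18  # floor(37/2)
        x = ad.Tensor(RNG.normal(size=(2, 37, 7, 200)))
        out = tr(x, train=True)
        assert out.data.shape == (2, 18, 4, 100)  # ceil(7/2)=4

    def test_compression_one_keeps_channels(self):
        cfg = _cfg()
        tr = Transition(10, 1.0, cfg, np.random.default_rng(0))
        assert tr.c_out == 10

    def test_pooling_against_hand_oracle(self):
        x = RNG.normal(size=(1, 2, 5, 7))
        out = ad.avgpool2x2_ceil(ad.Tensor(x)).data
        assert out.shape == (1, 2, 3, 4)
        for i in range(3):
            for j in range(4):
                window = x[:, :, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2]
                np.testing.assert_allclose(out[:, :, i, j], window.mean(axis=(2, 3)))

    def test_constant_input_pools_to_same_constant(self):
        x = np.full((1, 1, 7, 9), 3.25)
        out = ad.avgpool2x2_ceil(ad.Tensor(x)).data
        np.testing.assert_allclose(out, 3.25)


class TestBatchNorm:
    def _apply(self, x, gamma=1.0, beta=0.0, train=True):
        bn = BatchNorm2d(x.shape[1], eps=1e-5, momentum=0.1, dtype="float64")
        bn.gamma.data[...] = gamma
        bn.beta.data[...] = beta
        return bn(ad.Tensor(x), train=train).data

    def test_standardizes_in_train_mode(self):
        x = RNG.normal(loc=3, scale=2, size=(8, 3, 4, 5))
        y = self._apply(x)
        np.testing.assert_allclose(y.mean(axis=(0, 2, 3)), 0.0, atol=1e-10)
        np.testing.assert_allclose(y.var(axis=(0, 2, 3)), 1.0, atol=1e-4)

    def test_affine_parameters(self):
        x = RNG.normal(size=(16, 2, 3, 3))
        y = self._apply(x, gamma=2.0, beta=5.0)
        np.testing.assert_allclose(y.mean(axis=(0, 2, 3)), 5.0, atol=1e-10)
        np.testing.assert_allclose(y.std(axis=(0, 2, 3)), 2.0, atol=1e-3)

    def test_constant_channel_maps_to_beta(self):
        x = np.full((4, 1, 2, 2), 7.0)
        y = self._apply(x, beta=-1.5)
        np.testing.assert_allclose(y, -1.5, atol=1e-2)

    def test_eval_mode_uses_running_statistics(self):
        bn = BatchNorm2d(1, eps=1e-5, momentum=1.0, dtype="float64")
        x = RNG.normal(loc=10.0, size=(32, 1, 2, 2))
        bn(ad.Tensor(x), train=True)  # momentum 1 -> running stats = batch stats
        y = bn(ad.Tensor(x), train=False).data
        np.testing.assert_allclose(y.mean(), 0.0, atol=1e-6)

    def test_single_value_batch_rejected_in_train_mode(self):
        bn = BatchNorm2d(1, eps=1e-5, momentum=0.1, dtype="float64")
        with pytest.raises(ValueError):
            bn(ad.Tensor(np.ones((1, 1, 1, 1))), train=True)


class TestChannelAttention:
    def test_zero_parameters_give_half_weights(self):
        cfg = _cfg()
        att = _zero(ChannelAttention(8, 4, cfg, np.random.default_rng(0)))
        f = ad.Tensor(RNG.normal(size=(2, 8, 3, 5)))
        weights, fprime = att(f)
        np.testing.assert_allclose(weights.data, 0.5)
        np.testing.assert_allclose(fprime.data, 0.5 * f.data)

    def test_weights_in_open_unit_interval(self):
        cfg = _cfg()
        att = ChannelAttention(8, 4, cfg, np.random.default_rng(3))
        f = ad.Tensor(RNG.normal(size=(2, 8, 3, 5)) * 10)
        weights, _ = att(f)
        assert np.all(weights.data > 0) and np.all(weights.data < 1)

    def test_pure_per_channel_scaling(self):
        """Relative magnitudes within a channel are unchanged."""
        cfg = _cfg()
        att = ChannelAttention(4, 2, cfg, np.random.default_rng(4))
        f = ad.Tensor(RNG.normal(size=(1, 4, 3, 3)))
        weights, fprime = att(f)
        ratio = fprime.data / f.data
        for c in range(4):
            np.testing.assert_allclose(ratio[0, c], weights.data[0, c], rtol=1e-10)

    def test_constant_channel_makes_avg_equal_max(self):
        cfg = _cfg()
        att = ChannelAttention(2, 1, cfg, np.random.default_rng(5))
        f = np.ones((1, 2, 4, 4))
        avg = ad.global_avgpool(ad.Tensor(f)).data
        mx = ad.global_maxpool(ad.Tensor(f)).data
        np.testing.assert_array_equal(avg, mx)

    def test_reduction_larger_than_channels_rejected(self):
        cfg = _cfg()
        with pytest.raises(ValueError, match="reduction"):
            ChannelAttention(2, 4, cfg, np.random.default_rng(0))


class TestSpatialAttention:
    def test_zero_parameters_give_half_weights(self):
        cfg = _cfg()
        att = _zero(SpatialAttention(cfg, np.random.default_rng(0)))
        f = ad.Tensor(RNG.normal(size=(2, 6, 3, 9)))
        weights, fprime = att(f)
        np.testing.assert_allclose(weights.data, 0.5)
        np.testing.assert_allclose(fprime.data, 0.5 * f.data)

    def test_weights_shared_across_channels(self):
        cfg = _cfg()
        att = SpatialAttention(cfg, np.random.default_rng(1))
        f = ad.Tensor(RNG.normal(size=(1, 5, 4, 6)))
        weights, fprime = att(f)
        assert weights.data.shape == (1, 1, 4, 6)
        ratio = fprime.data / f.data
        for c in range(5):
            np.testing.assert_allclose(ratio[0, c], weights.data[0, 0], rtol=1e-10)

    def test_weights_in_open_unit_interval(self):
        cfg = _cfg()
        att = SpatialAttention(cfg, np.random.default_rng(2))
        f = ad.Tensor(RNG.normal(size=(3, 2, 5, 5)) * 4)
        weights, _ = att(f)
        assert np.all(weights.data > 0) and np.all(weights.data < 1)


class TestParallelCombination:
    def test_zero_parameterized_modules_give_quarter_square(self):
        cfg = _cfg(attention_variant="parallel")
        stage = _zero(AttentionStage(8, cfg, np.random.default_rng(0)))
        f = ad.Tensor(RNG.normal(size=(2, 8, 3, 4)))
        out = stage(f)
        np.testing.assert_allclose(out.data, 0.25 * f.data * f.data)

    def test_zero_input_gives_zero_output(self):
        cfg = _cfg()
        stage = AttentionStage(8, cfg, np.random.default_rng(1))
        f = ad.Tensor(np.zeros((1, 8, 2, 3)))
        assert np.all(stage(f).data == 0.0)

    @pytest.mark.parametrize("variant", ["parallel", "serial", "channel", "spatial"])
    def test_shape_preserved(self, variant):
        cfg = _cfg(attention_variant=variant)
        stage = AttentionStage(8, cfg, np.random.default_rng(2))
        f = ad.Tensor(RNG.normal(size=(2, 8, 3, 7)))
        assert stage(f).data.shape == f.data.shape

    def test_joint_mask_alternative(self):
        cfg = _cfg(attention_combine="joint_mask")
        stage = _zero(AttentionStage(4, cfg, np.random.default_rng(3)))
        f = ad.Tensor(RNG.normal(size=(1, 4, 2, 3)))
        np.testing.assert_allclose(stage(f).data, 0.25 * f.data)


class TestHeadAndSoftmax:
    def test_equal_logits_give_half_half(self):
        np.testing.assert_allclose(ad.softmax(np.zeros((3, 2))), 0.5)

    def test_closed_form_evaluation(self):
        p = ad.softmax(np.array([[0.0, math.log(2.0)]]))
        np.testing.assert_allclose(p, [[1 / 3, 2 / 3]], rtol=1e-12)

    def test_probabilities_sum_to_one(self, tiny_cfg):
        model = build_model(tiny_cfg)
        x = RNG.random(size=(4, 1, 7, 40))
        probs = model.predict_proba(x)
        assert probs.shape == (4, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-10)


class TestBuildModel:
    def test_default_model_has_twelve_dense_layers(self):
        model = build_model(NetworkConfig())
        n_layers = sum(len(b.layers) for b in model.blocks)
        assert n_layers == 12  # four dense blocks x three conv layers

    def test_channel_bookkeeping_matches_closed_form(self):
        cfg = NetworkConfig()
        trace = channel_trace(cfg, c_in=1)
        model = build_model(cfg)
        for entry, block in zip(trace, model.blocks):
            assert block.c_out == entry["out"]
        for entry, tr in zip(trace[:-1], model.transitions):
            assert tr.c_out == entry["after_transition"]
        # closed form c_{b+1} = floor((c_b + L*k) * compression)
        c = 1
        for b in range(cfg.num_blocks):
            c_out = c + cfg.layers_per_block * cfg.growth_rate
            assert trace[b]["out"] == c_out
            if b < cfg.num_blocks - 1:
                c = int(np.floor(c_out * cfg.transition_compression))
                assert trace[b]["after_transition"] == c

    def test_no_attention_variant_has_no_attention_parameters(self):
        with_att = build_model(_cfg(use_attention=True))
        without = build_model(_cfg(use_attention=False))
        assert without.attention is None
        n_att = len(with_att.attention.params())
        assert len(with_att.params()) - len(without.params()) == n_att

    def test_forward_returns_one_probability_pair_per_input(self, tiny_cfg):
        model = build_model(tiny_cfg)
        probs = model.predict_proba(RNG.random(size=(5, 1, 7, 200)).astype(np.float64))
        assert probs.shape == (5, 2)

    def test_eval_forward_is_deterministic(self, tiny_cfg):
        model = build_model(tiny_cfg)
        x = RNG.random(size=(3, 1, 7, 50))
        p1 = model.predict_proba(x)
        p2 = model.predict_proba(x)
        np.testing.assert_array_equal(p1, p2)

    def test_same_seed_builds_identical_models(self, tiny_cfg):
        x = RNG.random(size=(2, 1, 7, 30))
        p1 = build_model(tiny_cfg).predict_proba(x)
        p2 = build_model(tiny_cfg).predict_proba(x)
        np.testing.assert_array_equal(p1, p2)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(transition_compression=0.0)
        with pytest.raises(ValueError):
            NetworkConfig(num_blocks=0)
        with pytest.raises(ValueError):
            NetworkConfig(attention_variant="cascade")

    def test_resnet_baseline_forward(self, tiny_cfg):
        model = build_model(tiny_cfg, backbone="resnet")
        probs = model.predict_proba(RNG.random(size=(2, 1, 7, 40)))
        assert probs.shape == (2, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-10)


class TestGradients:
    def _loss_fn(self, model, x, y):
        logits = model.forward(x, train=True)
        loss, _ = ad.softmax_cross_entropy(logits, y)
        return loss

    def test_numerical_vs_analytic_gradients(self, tiny_cfg):
        """Finite-difference oracle on a tiny model (all parameter groups)."""
        model = build_model(tiny_cfg)
        x = np.random.default_rng(11).normal(size=(3, 1, 5, 12))
        y = np.array([0, 1, 1])
        loss = self._loss_fn(model, x, y)
        ad.backward(loss)
        grads = [p.grad.copy() if p.grad is not None else np.zeros_like(p.data)
                 for p in model.params()]
        h = 1e-6
        rng = np.random.default_rng(0)
        checked = 0
        for p, g in zip(model.params(), grads):
            flat = p.data.reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                lp = float(self._loss_fn(model, x, y).data)
                flat[idx] = orig - h
                lm = float(self._loss_fn(model, x, y).data)
                flat[idx] = orig
                num = (lp - lm) / (2 * h)
                ana = g.reshape(-1)[idx]
                assert math.isclose(num, ana, rel_tol=1e-4, abs_tol=1e-7), (
                    f"gradient mismatch: numeric {num} vs analytic {ana}"
                )
                checked += 1
        assert checked >= 30
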