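import math

import numpy as np
import pytest

from mscformer import MSNet, NetworkConfig, build_model, count_parameters, pooled_length
from mscformer.autograd import Tensor
from mscformer.model import _avg_pool_time


def tiny_cfg(**kw):
    base = dict(
        channels=3, samples=60, n_classes=2, f1=2, heads=2, ff_dim=12, pool=12,
        depth=1, conv_dropout=0.0, encoder_dropout=0.0, classifier_dropout=0.0,
    )
    base.update(kw)
    return NetworkConfig(**base)


class TestTokenGeometry:
    @pytest.mark.parametrize("pool,expected", [(12, 84), (72, 14)])
    def test_pooled_token_length_at_benchmark_sizes(self, pool, expected):
        assert pooled_length(1000, pool) == expected

    def test_conv_module_emits_that_many_tokens(self):
        cfg = NetworkConfig(
            channels=4, samples=1000, n_classes=2, f1=2, heads=2, ff_dim=12,
            pool=12, depth=1,
        )
        model = build_model(cfg)
        x = Tensor(np.random.default_rng(0).standard_normal((1, 4, 1000)))
        tokens = model.conv_tokens(x, train=False, rng=np.random.default_rng(0))
        assert tokens.shape == (1, 84, cfg.embed_dim)

    def test_embed_dim_is_three_f1(self):
        assert NetworkConfig(f1=16).embed_dim == 48
        assert tiny_cfg(f1=2).embed_dim == 6

    def test_fuse_concatenation_order(self):
        # constant branch outputs a,a | b,b | c,c per token
        cfg = tiny_cfg()
        model = build_model(cfg)
        from mscformer.autograd import concat

        a = Tensor(np.full((1, 2, 3), 1.0))
        b = Tensor(np.full((1, 2, 3), 2.0))
        c = Tensor(np.full((1, 2, 3), 3.0))
        tokens = concat([a, b, c], axis=1).transpose((0, 2, 1)).data
        np.testing.assert_array_equal(tokens[0, 0], [1, 1, 2, 2, 3, 3])

    def test_zero_input_with_zero_biases_gives_zero_maps(self):
        # linearity: BN in inference mode with zero biases passes zeros through
        cfg = tiny_cfg()
        model = build_model(cfg, seed=0)
        for br in model.branches:
            br.bt.data[:] = 0
            br.bs.data[:] = 0
        rng = np.random.default_rng(0)
        x = Tensor(np.zeros((1, cfg.channels, cfg.samples)))
        tokens = model.conv_tokens(x, train=False, rng=rng)
        np.testing.assert_allclose(tokens.data, 0.0, atol=1e-12)

    def test_avg_pool_partial_window_uses_actual_count(self):
        x = Tensor(np.arange(5.0)[None])
        out = _avg_pool_time(x, 2, ceil_mode=True).data
        np.testing.assert_allclose(out[0], [0.5, 2.5, 4.0])
        out_floor = _avg_pool_time(x, 2, ceil_mode=False).data
        np.testing.assert_allclose(out_floor[0], [0.5, 2.5])


class TestParameterAccounting:
    def test_published_counts_reproduced(self):
        # full network counts are token-length independent (operator weights)
        assert count_parameters(NetworkConfig(), as_thousands=True) == 145.9
        assert (
            count_parameters(
                NetworkConfig(channels=3, n_classes=2, pool=52), as_thousands=True
            )
            == 144.9
        )
        # ablation counts depend on the flatten length (floor-mode convention)
        assert (
            count_parameters(
                NetworkConfig(pool_ceil_mode=False), "msnet", as_thousands=True
            )
            == 8.6
        )
        assert (
            count_parameters(
                NetworkConfig(channels=3, n_classes=2, pool=52, pool_ceil_mode=False),
                "msnet",
                as_thousands=True,
            )
            == 5.3
        )

    def test_toy_config_count_matches_closed_form(self):
        cfg = tiny_cfg(depth=1)
        f1, c, kc = cfg.f1, cfg.channels, cfg.kernels
        conv = sum(f1 * k + f1 + f1 * c + f1 + 2 * f1 for k in kc)
        e, ff, m = cfg.embed_dim, cfg.ff_dim, cfg.n_classes
        layer = 3 * (e * e + e) + e * e + e + (e * ff + ff) + (ff * e + e) + 4 * e
        clf = e * m + m
        assert count_parameters(cfg) == conv + layer + clf
        embeddings = e + (cfg.n_tokens + 1) * e
        assert count_parameters(cfg, include_embeddings=True) == (
            conv + layer + clf + embeddings
        )

    def test_geometry_difference_has_closed_form(self):
        cfg_a = NetworkConfig(pool_ceil_mode=False)
        cfg_b = NetworkConfig(channels=3, n_classes=2, pool=52, pool_ceil_mode=False)
        full_a = count_parameters(cfg_a, include_embeddings=True)
        full_b = count_parameters(cfg_b, include_embeddings=True)
        e = cfg_a.embed_dim
        expected = (
            3 * cfg_a.f1 * (cfg_a.channels - cfg_b.channels)  # spatial kernels
            + (e + 1) * (cfg_a.n_classes - cfg_b.n_classes)  # classifier width
            + e * (cfg_a.n_tokens - cfg_b.n_tokens)  # positional-table length
        )
        assert full_a - full_b == expected


class TestAttentionContracts:
    def test_attention_rows_sum_to_one_every_layer_and_head(self):
        cfg = tiny_cfg(depth=2)
        model = build_model(cfg, seed=3)
        rng = np.random.default_rng(0)
        seq = Tensor(rng.standard_normal((2, 5, cfg.embed_dim)))
        for layer in model.layers:
            h, dk = cfg.heads, cfg.head_dim
            N, S, E = seq.shape

            def split(t):
                return t.reshape(N, S, h, dk).transpose((0, 2, 1, 3))

            q = split(layer["wq"](seq))
            k = split(layer["wk"](seq))
            scores = (q @ k.transpose((0, 1, 3, 2))) * (1.0 / math.sqrt(dk))
            attn = scores.softmax(axis=-1).data
            np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-6)
            seq = model._mha_block(seq, layer, False, rng)
            seq = model._ff_block(seq, layer, False, rng)

    def test_single_token_attention_returns_value_row(self):
        # softmax over a singleton is exactly 1 -> context == V
        q = Tensor(np.array([[[[1.0]]]]))
        k = Tensor(np.array([[[[2.0]]]]))
        v = Tensor(np.array([[[[7.0]]]]))
        attn = ((q @ k.transpose((0, 1, 3, 2))) * 1.0).softmax(axis=-1)
        np.testing.assert_allclose((attn @ v).data, v.data)

    def test_identical_tokens_give_uniform_weights(self):
        n, dk = 4, 3
        q = Tensor(np.tile(np.ones((1, 1, 1, dk)), (1, 1, n, 1)))
        attn = ((q @ q.transpose((0, 1, 3, 2))) * (1 / math.sqrt(dk))).softmax(-1)
        np.testing.assert_allclose(attn.data, 1.0 / n, atol=1e-12)

    def test_two_token_case_matches_dense_oracle(self):
        qkv = np.array([[1.0], [0.0]])
        scores = qkv @ qkv.T / 1.0
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        w = e / e.sum(axis=1, keepdims=True)
        expected = w @ qkv
        t = Tensor(qkv[None, None])
        attn = ((t @ t.transpose((0, 1, 3, 2))) * 1.0).softmax(-1) @ t
        np.testing.assert_allclose(attn.data[0, 0], expected, atol=1e-9)

    def test_post_norm_residual_zero_ff_weights_reduce_to_layernorm(self):
        cfg = tiny_cfg()
        model = build_model(cfg, seed=0)
        layer = model.layers[0]
        layer["w1"].w.data[:] = 0
        layer["w1"].b.data[:] = 0
        layer["w2"].w.data[:] = 0
        layer["w2"].b.data[:] = 0
        rng = np.random.default_rng(0)
        seq = Tensor(rng.standard_normal((1, 4, cfg.embed_dim)))
        out = model._ff_block(seq, layer, False, rng)
        expected = layer["ln2"](seq).data
        np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_encoder_is_permutation_equivariant_without_positions(self):
        cfg = tiny_cfg(depth=2)
        model = build_model(cfg, seed=5)
        rng = np.random.default_rng(1)
        tokens = rng.standard_normal((1, 5, cfg.embed_dim))
        perm = np.array([3, 0, 4, 1, 2])

        def encode(arr):
            return model.encode(
                Tensor(arr), train=False, rng=np.random.default_rng(0),
                use_positions=False, use_class_token=False,
            ).data

        out = encode(tokens)
        out_perm = encode(tokens[:, perm])
        np.testing.assert_allclose(out_perm, out[:, perm], atol=1e-9)


class TestForwardContracts:
    def test_probabilities_normalized(self):
        cfg = tiny_cfg()
        model = build_model(cfg)
        x = np.random.default_rng(0).standard_normal((4, 3, 60))
        p = model.forward(x)
        assert p.shape == (4, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_output_width_matches_class_count(self):
        for m in (2, 4):
            cfg = tiny_cfg(n_classes=m)
            p = build_model(cfg).forward(np.zeros((3, 60)))
            assert p.shape == (m,)

    def test_eval_forward_is_deterministic(self):
        cfg = tiny_cfg(conv_dropout=0.5, encoder_dropout=0.25, classifier_dropout=0.25)
        model = build_model(cfg)
        x = np.random.default_rng(0).standard_normal((2, 3, 60))
        a = model.forward(x, train=False)
        b = model.forward(x, train=False)
        np.testing.assert_array_equal(a, b)

    def test_channel_mismatch_raises(self):
        model = build_model(tiny_cfg())
        with pytest.raises(ValueError, match="channels"):
            model.forward(np.zeros((1, 5, 60)))

    def test_depth_zero_mscformer_rejected(self):
        with pytest.raises(ValueError, match="MSNet"):
            build_model(tiny_cfg(depth=0))

    def test_heads_must_divide_embed_dim(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(f1=2, heads=4)

    def test_msnet_flatten_length_and_probabilities(self):
        cfg = tiny_cfg()
        model = build_model(cfg, "msnet")
        assert isinstance(model, MSNet)
        assert model.classifier.w.shape == (
            cfg.n_tokens * cfg.embed_dim,
            cfg.n_classes,
        )
        p = model.forward(np.zeros((2, 3, 60)))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_one_training_step_decreases_loss(self):
        from mscformer.train import TrainConfig, _Adam

        cfg = tiny_cfg()
        model = build_model(cfg, seed=2)
        rng = np.random.default_rng(3)
        x = rng.standard_normal((8, 3, 60))
        y = rng.integers(0, 2, size=8)
        opt = _Adam(model.params, TrainConfig(lr=1e-3, epochs=1, batch_size=8))
        before = float(model.loss(x, y, train=True).data)
        loss = model.loss(x, y, train=True)
        loss.backward()
        opt.step()
        after = float(model.loss(x, y, train=True).data)
        assert after < before
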